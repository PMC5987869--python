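"""ROI-based multivoxel pattern analysis of subject group membership.

The analysis asks whether spatial activation patterns carry diagnostic group
information, and whether different learning disorders deviate from controls
in a *similar* pattern direction:

* **Subject classification** -- a linear classifier separates two groups of
  subjects under leave-pair-out cross-validation (LPOCV): groups are first
  rebalanced by subsampling the larger group to the smaller size *n*, the
  balanced groups are matched into *n* disjoint random test pairs, and each
  pair is held out in turn while the classifier trains on the remaining
  2(n-1) subjects.  One such pass yields an accuracy over all 2n subjects;
  the procedure is repeated (default 1000 times) and averaged.
* **Permutation significance** -- a Monte-Carlo null repeats the LPOCV pass
  with the *training* labels randomly permuted (test subjects keep their true
  labels for scoring).  The significance cutoff is the 95th percentile of the
  null accuracies; an observed mean accuracy above it is significant.
* **Subject generalization** -- a classifier trained to separate controls
  from disorder group X is tested on separating controls from disorder group
  Y, in both directions, and the directional accuracies are averaged.  It can
  only beat its permutation cutoff if X and Y deviate from controls along
  similar pattern directions.

Patterns are ROI-restricted contrast estimates, mean-centered within each
subject so that global activation-level differences between subjects cannot
drive the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_SELECTORS = {
    "TD": lambda g: g == "TD",
    "DL": lambda g: g == "DL",
    "DC": lambda g: g == "DC",
    "DLDC": lambda g: g == "DLDC",
    "DL+DLDC": lambda g: np.isin(g, ["DL", "DLDC"]),
    "DC+DLDC": lambda g: np.isin(g, ["DC", "DLDC"]),
}

#: the six classification comparisons run per ROI and format
CLASSIFICATION_COMPARISONS = (
    ("TD", "DL+DLDC"),
    ("TD", "DC+DLDC"),
    ("TD", "DL"),
    ("TD", "DC"),
    ("TD", "DLDC"),
    ("DL", "DC"),
)

#: the three generalization pairs run per ROI and format (controls = TD)
GENERALIZATION_PAIRS = (("DL", "DC"), ("DL", "DLDC"), ("DC", "DLDC"))


# ---------------------------------------------------------------------------
# pattern extraction
# ---------------------------------------------------------------------------


@dataclass
class PatternMatrix:
    """Subjects x voxels matrix of ROI-restricted contrast values."""

    values: np.ndarray
    labels: np.ndarray  # per-subject group name
    subject_ids: np.ndarray
    roi_name: str = ""
    contrast_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError(f"pattern values must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern matrix contains non-finite values")
        if len(self.labels) != self.values.shape[0] or len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("labels/subject_ids must match the number of rows")

    def group_indices(self, name: str) -> np.ndarray:
        try:
            sel = GROUP_SELECTORS[name]
        except KeyError:
            raise KeyError(f"unknown group selector {name!r}; known: {sorted(GROUP_SELECTORS)}") from None
        return np.flatnonzero(sel(self.labels))


def extract_patterns(
    contrast_maps: dict,
    roi_mask: np.ndarray,
    roi_name: str = "",
    labels: dict | None = None,
    contrast_label: str = "",
) -> PatternMatrix:
    """Stack in-ROI contrast values into a subjects x voxels matrix.

    ``contrast_maps`` maps subject_id to a 3D array (or an object with a
    ``.values`` grid); voxel order is the fixed C-order scan of the ROI mask.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError(f"ROI {roi_name!r} is empty")
    idx = np.flatnonzero(roi_mask.ravel())
    sids, rows, labs = [], [], []
    for sid, cmap in contrast_maps.items():
        grid = cmap.values if hasattr(cmap, "values") else np.asarray(cmap)
        if grid.shape != roi_mask.shape:
            raise ValueError(f"map for {sid} has shape {grid.shape} != ROI {roi_mask.shape}")
        rows.append(grid.ravel()[idx])
        sids.append(sid)
        labs.append(labels[sid] if labels else "")
    return PatternMatrix(
        values=np.vstack(rows),
        labels=np.array(labs),
        subject_ids=np.array(sids),
        roi_name=roi_name,
        contrast_label=contrast_label,
    )


def mean_center_subject(patterns: PatternMatrix) -> PatternMatrix:
    """Remove each subject's mean activation level across the ROI's voxels."""
    centered = patterns.values - patterns.values.mean(axis=1, keepdims=True)
    return PatternMatrix(
        values=centered,
        labels=patterns.labels,
        subject_ids=patterns.subject_ids,
        roi_name=patterns.roi_name,
        contrast_label=patterns.contrast_label,
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

try:
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


def _svm_dual_cd_py(Xb, y, C, tol, max_sweeps):
    """Dual coordinate descent for the L2-regularized squared-hinge SVM.

    Solves min_a 1/2 a' (Q + I/(2C)) a - e'a, a >= 0 with Q_ij = y_i y_j
    x_i'x_j over bias-augmented features -- the same strictly convex dual the
    liblinear L2R_L2LOSS_SVC_DUAL solver optimizes, so the unique primal
    weight vector matches sklearn's ``LinearSVC`` to solver tolerance.
    """
    n, d = Xb.shape
    alpha = np.zeros(n)
    w = np.zeros(d)
    dii = 1.0 / (2.0 * C)
    qd = np.empty(n)
    for i in range(n):
        s = dii
        for j in range(d):
            s += Xb[i, j] * Xb[i, j]
        qd[i] = s
    for _ in range(max_sweeps):
        max_pg = 0.0
        for i in range(n):
            g = 0.0
            for j in range(d):
                g += w[j] * Xb[i, j]
            g = g * y[i] - 1.0 + dii * alpha[i]
            pg = min(g, 0.0) if alpha[i] == 0.0 else g
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if abs(pg) > 1e-14:
                old = alpha[i]
                new = old - g / qd[i]
                if new < 0.0:
                    new = 0.0
                alpha[i] = new
                step = (new - old) * y[i]
                if step != 0.0:
                    for j in range(d):
                        w[j] += step * Xb[i, j]
        if max_pg < tol:
            break
    return w


if _numba is not None:
    _svm_dual_cd = _numba.njit(cache=True, fastmath=False)(_svm_dual_cd_py)
else:  # pragma: no cover
    _svm_dual_cd = _svm_dual_cd_py


class LinearSVMClassifier:
    """Soft-margin linear SVM, C = 1 (squared hinge, regularized intercept).

    Fitting runs a compiled dual coordinate-descent solver for the same
    objective liblinear's dual solver optimizes; the resampling procedures in
    this module fit the classifier hundreds of thousands of times, which
    rules out per-call estimator construction.  Features are centered on the
    training mean before fitting: the intercept is part of the regularized
    weight vector, which otherwise biases the boundary when both classes
    share a large common offset.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-6, max_sweeps: int = 2000):
        self.C = C
        self.tol = tol
        self.max_sweeps = max_sweeps

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        self.center_ = X.mean(axis=0)
        Xb = np.empty((X.shape[0], X.shape[1] + 1))
        Xb[:, :-1] = X - self.center_
        Xb[:, -1] = 1.0  # bias feature (regularized, liblinear convention)
        ypm = np.where(np.asarray(y) > 0, 1.0, -1.0)
        w = _svm_dual_cd(Xb, ypm, self.C, self.tol, self.max_sweeps)
        self.coef_ = w[:-1]
        self.intercept_ = float(w[-1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center_) @ self.coef_ + self.intercept_


class LDAClassifier:
    """Linear discriminant with pooled covariance (pseudo-inverse for n < p)."""

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, float)
        y = np.asarray(y)
        X0, X1 = X[y == 0], X[y == 1]
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        Xc = np.vstack([X0 - m0, X1 - m1])
        cov = (Xc.T @ Xc) / max(len(X) - 2, 1)
        cov.flat[:: cov.shape[0] + 1] += 1e-6 * max(np.trace(cov) / cov.shape[0], 1e-12)
        w = np.linalg.pinv(cov) @ (m1 - m0)
        self.coef_ = w
        self.intercept_ = -0.5 * float(w @ (m0 + m1))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_ + self.intercept_


def _make_classifier(name: str):
    if name == "linear_svm":
        return LinearSVMClassifier()
    if name == "lda":
        return LDAClassifier()
    raise ValueError(f"classifier must be 'linear_svm' or 'lda', got {name!r}")


# ---------------------------------------------------------------------------
# LPOCV machinery
# ---------------------------------------------------------------------------


@dataclass
class LPOCVConfig:
    n_repetitions: int = 1000
    n_permutations: int = 1000
    classifier: str = "linear_svm"
    balance: bool = True
    seed: int = 0
    pairing: str = "bijection"  # or 'all_pairs'
    permute_mode: str = "training"  # or 'full'

    def __post_init__(self):
        if self.n_repetitions < 1 or self.n_permutations < 1:
            raise ValueError("repetition and permutation counts must be >= 1")
        if self.pairing not in ("bijection", "all_pairs"):
            raise ValueError(f"pairing must be 'bijection' or 'all_pairs', got {self.pairing!r}")
        if self.permute_mode not in ("training", "full"):
            raise ValueError(f"permute_mode must be 'training' or 'full', got {self.permute_mode!r}")


def _predict_pair(clf, X_train, y_train, X_test, y_test) -> int:
    """Fit and score one held-out pair; returns the number of correct calls.

    A decision score of exactly zero is deterministically assigned to class 0.
    Degenerate all-one-class training labels predict that class throughout.
    """
    classes = np.unique(y_train)
    if classes.size == 1:
        pred = np.full(len(y_test), classes[0])
    else:
        clf.fit(X_train, y_train)
        pred = (clf.decision_function(X_test) > 0).astype(int)
    return int((pred == y_test).sum())


def _lpocv_pass(XA, XB, clf, rng, train_labels: np.ndarray | None = None, pairing: str = "bijection") -> float:
    """One LPOCV pass over balanced groups; returns test accuracy.

    ``XA``/``XB`` are (n, V).  With 'bijection' pairing, a random matching
    gives n disjoint test pairs covering every subject exactly once; with
    'all_pairs' every cross-group pair is held out in turn.  If
    ``train_labels`` (length 2n, rows of A then B) is given, training uses
    those labels while scoring keeps the truth.
    """
    n = XA.shape[0]
    X = np.vstack([XA, XB])
    y_true = np.repeat([0, 1], n)
    y_train_src = y_true if train_labels is None else np.asarray(train_labels)
    correct = 0
    total = 0
    if pairing == "bijection":
        perm = rng.permutation(n)
        pairs = [(i, n + perm[i]) for i in range(n)]
    else:
        pairs = [(i, n + j) for i in range(n) for j in range(n)]
    keep = np.empty(2 * n, bool)
    for i, j in pairs:
        keep[:] = True
        keep[i] = keep[j] = False
        correct += _predict_pair(clf, X[keep], y_train_src[keep], X[[i, j]], y_true[[i, j]])
        total += 2
    return correct / total


def _balanced_views(patterns: PatternMatrix, group_a: str, group_b: str, rng, balance: bool):
    ia, ib = patterns.group_indices(group_a), patterns.group_indices(group_b)
    shared = np.intersect1d(ia, ib)
    if shared.size:
        ia = np.setdiff1d(ia, shared)
        ib = np.setdiff1d(ib, shared)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"groups {group_a!r} ({len(ia)}) and {group_b!r} ({len(ib)}) need >= 2 disjoint subjects each"
        )
    n = min(len(ia), len(ib)) if balance else min(len(ia), len(ib))
    sa = rng.choice(ia, size=n, replace=False) if len(ia) > n else ia
    sb = rng.choice(ib, size=n, replace=False) if len(ib) > n else ib
    return patterns.values[sa], patterns.values[sb]


@dataclass
class ClassificationResult:
    mean_accuracy: float
    null_distribution: np.ndarray
    cutoff_95: float
    significant: bool
    comparison_label: str = ""
    roi_name: str = ""
    contrast_label: str = ""
    accuracies: np.ndarray = field(default_factory=lambda: np.array([]))


def lpocv_accuracies(patterns: PatternMatrix, group_a: str, group_b: str, config: LPOCVConfig, rng=None, permute: bool = False, n_iter: int | None = None) -> np.ndarray:
    """Repeated LPOCV pass accuracies (optionally with permuted training labels)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clf = _make_classifier(config.classifier)
    n_iter = n_iter if n_iter is not None else (config.n_permutations if permute else config.n_repetitions)
    out = np.empty(n_iter)
    for k in range(n_iter):
        XA, XB = _balanced_views(patterns, group_a, group_b, rng, config.balance)
        n = XA.shape[0]
        labels = rng.permutation(np.repeat([0, 1], n)) if permute else None
        out[k] = _lpocv_pass(XA, XB, clf, rng, train_labels=labels, pairing=config.pairing)
    return out


def lpocv_classify(patterns: PatternMatrix, group_a: str, group_b: str, config: LPOCVConfig | None = None, rng=None) -> float:
    """Mean LPOCV accuracy over ``config.n_repetitions`` repetitions."""
    config = config or LPOCVConfig()
    return float(lpocv_accuracies(patterns, group_a, group_b, config, rng=rng, permute=False).mean())


def permutation_cutoff(patterns: PatternMatrix, group_a: str, group_b: str, config: LPOCVConfig | None = None, rng=None) -> tuple[np.ndarray, float]:
    """Monte-Carlo null accuracies and their 95th-percentile cutoff."""
    config = config or LPOCVConfig()
    null = lpocv_accuracies(patterns, group_a, group_b, config, rng=rng, permute=True)
    return null, float(np.percentile(null, 95))


def classify_groups(patterns: PatternMatrix, group_a: str, group_b: str, config: LPOCVConfig | None = None, rng=None) -> ClassificationResult:
    """Full classification cell: observed LPOCV accuracy versus permutation null."""
    config = config or LPOCVConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    accs = lpocv_accuracies(patterns, group_a, group_b, config, rng=rng, permute=False)
    null, cutoff = permutation_cutoff(patterns, group_a, group_b, config, rng=rng)
    mean_acc = float(accs.mean())
    return ClassificationResult(
        mean_accuracy=mean_acc,
        null_distribution=null,
        cutoff_95=cutoff,
        significant=bool(mean_acc > cutoff),
        comparison_label=f"{group_a}_vs_{group_b}",
        roi_name=patterns.roi_name,
        contrast_label=patterns.contrast_label,
        accuracies=accs,
    )


# ---------------------------------------------------------------------------
# cross-disorder generalization
# ---------------------------------------------------------------------------


@dataclass
class GeneralizationResult:
    acc_train_x_test_y: float
    acc_train_y_test_x: float
    mean_accuracy: float
    null_distribution: np.ndarray
    cutoff_95: float
    significant: bool
    comparison_label: str = ""
    roi_name: str = ""
    contrast_label: str = ""


def _generalization_pass(values, td_idx, train_idx, test_idx, clf, rng, permute: bool = False) -> float:
    """One directional generalization pass (train control-vs-X, test control-vs-Y).

    Each fold holds out one control subject paired with one test-group
    subject; the classifier trains on the remaining control subjects versus
    the training-group subsample.  Any test-pair subject present in the
    training pool is dropped from that fold's training set, so no subject is
    ever both trained and tested on -- which also makes the degenerate case
    Y = X reduce to ordinary leave-pair-out classification.
    """
    n = len(td_idx)
    perm = rng.permutation(n)  # match control folds to test-group subjects
    pool = np.concatenate([td_idx, train_idx])
    y_pool = np.repeat([0, 1], n)
    labels = rng.permutation(y_pool) if permute else y_pool
    y_test = np.array([0, 1])
    correct = 0
    keep = np.empty(2 * n, bool)
    for i in range(n):
        test_ctrl, test_dis = td_idx[i], test_idx[perm[i]]
        keep[:] = True
        keep[i] = False
        keep[pool == test_dis] = False
        correct += _predict_pair(clf, values[pool[keep]], labels[keep], values[[test_ctrl, test_dis]], y_test)
    return correct / (2 * n)


def generalize(
    patterns: PatternMatrix,
    group_x: str,
    group_y: str,
    config: LPOCVConfig | None = None,
    control_group: str = "TD",
    rng=None,
) -> GeneralizationResult:
    """Bidirectional subject generalization between two disorder groups.

    Trains control-versus-X and tests on control-versus-Y (and vice versa),
    balancing all three groups to the smallest size each repetition; the mean
    of the two directional accuracies is compared against a permutation null
    built with permuted training labels.
    """
    config = config or LPOCVConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clf = _make_classifier(config.classifier)
    itd = patterns.group_indices(control_group)
    ix = patterns.group_indices(group_x)
    iy = patterns.group_indices(group_y)
    for b in (ix, iy):
        if np.intersect1d(itd, b).size:
            raise ValueError("control group must be disjoint from both disorder groups")
    if min(len(itd), len(ix), len(iy)) < 2:
        raise ValueError("each group needs >= 2 subjects")
    n = min(len(itd), len(ix), len(iy))
    values = patterns.values

    def draw():
        td = rng.choice(itd, n, replace=False)
        x = rng.choice(ix, n, replace=False)
        y = rng.choice(iy, n, replace=False)
        return td, x, y

    acc_xy = np.empty(config.n_repetitions)
    acc_yx = np.empty(config.n_repetitions)
    for k in range(config.n_repetitions):
        td, x, y = draw()
        acc_xy[k] = _generalization_pass(values, td, x, y, clf, rng)
        acc_yx[k] = _generalization_pass(values, td, y, x, clf, rng)
    null = np.empty(config.n_permutations)
    for k in range(config.n_permutations):
        td, x, y = draw()
        a = _generalization_pass(values, td, x, y, clf, rng, permute=True)
        b = _generalization_pass(values, td, y, x, clf, rng, permute=True)
        null[k] = 0.5 * (a + b)
    mean_acc = float(0.5 * (acc_xy.mean() + acc_yx.mean()))
    cutoff = float(np.percentile(null, 95))
    return GeneralizationResult(
        acc_train_x_test_y=float(acc_xy.mean()),
        acc_train_y_test_x=float(acc_yx.mean()),
        mean_accuracy=mean_acc,
        null_distribution=null,
        cutoff_95=cutoff,
        significant=bool(mean_acc > cutoff),
        comparison_label=f"{group_x}<->{group_y}",
        roi_name=patterns.roi_name,
        contrast_label=patterns.contrast_label,
    )


# ---------------------------------------------------------------------------
# full suite
# ---------------------------------------------------------------------------


def run_mvpa_suite(
    pattern_matrices: dict,
    config: LPOCVConfig | None = None,
    comparisons=CLASSIFICATION_COMPARISONS,
    generalization_pairs=GENERALIZATION_PAIRS,
    mean_center: bool = True,
) -> pd.DataFrame:
    """Run every classification and generalization cell.

    ``pattern_matrices`` maps ``(roi_name, contrast_label)`` to a
    PatternMatrix.  Returns one row per ROI x contrast x comparison with the
    observed accuracy, permutation cutoff and significance flag; cells whose
    groups are missing are skipped with a warning.  Deterministic given
    ``config.seed``.
    """
    import warnings

    config = config or LPOCVConfig()
    rows = []
    results = {}
    for ci, ((roi, fmt), pm) in enumerate(sorted(pattern_matrices.items())):
        if mean_center:
            pm = mean_center_subject(pm)
        for gi, (a, b) in enumerate(comparisons):
            rng = np.random.default_rng([config.seed, 11, ci, gi])
            try:
                res = classify_groups(pm, a, b, config, rng=rng)
            except (ValueError, KeyError) as e:
                warnings.warn(f"classification {a} vs {b} in {roi}/{fmt} skipped: {e}")
                continue
            results[(roi, fmt, "classification", f"{a}_vs_{b}")] = res
            rows.append((roi, fmt, "classification", f"{a}_vs_{b}", res.mean_accuracy, res.cutoff_95, res.significant))
        for gi, (x, y) in enumerate(generalization_pairs):
            rng = np.random.default_rng([config.seed, 13, ci, gi])
            try:
                res = generalize(pm, x, y, config, rng=rng)
            except (ValueError, KeyError) as e:
                warnings.warn(f"generalization {x}<->{y} in {roi}/{fmt} skipped: {e}")
                continue
            results[(roi, fmt, "generalization", f"{x}<->{y}")] = res
            rows.append((roi, fmt, "generalization", f"{x}<->{y}", res.mean_accuracy, res.cutoff_95, res.significant))
    table = pd.DataFrame(
        rows, columns=["roi", "contrast", "analysis", "comparison", "accuracy", "cutoff_95", "significant"]
    )
    table.attrs["results"] = results
    return table
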