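"""Voxelwise group statistics on first-level contrast maps.

A 2 x 2 between-subject factorial ANOVA (presence of dyslexia x presence of
dyscalculia) is fitted per voxel, with Type III sums of squares computed by
model comparison on an effect-coded design (the four cells are unbalanced:
22/14/8/8 by default).  Directional two-sample t maps cover the
control-versus-disorder comparisons, and thresholding is voxel-level
Benjamini-Hochberg FDR (q = 0.05) or uncorrected p < 0.001, both strict.
Analysis is restricted to an in-brain mask so the FDR denominator excludes
background voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

FACTORIAL_EFFECTS = ("DL_main", "DC_main", "DLxDC")

#: directional comparisons: (label, selector for group 1, selector for group 2)
#: where a selector maps (dyslexia, dyscalculia) bool arrays to a subject mask
DIRECTIONAL_COMPARISONS = {
    "TD_gt_DL+DLDC": (lambda dl, dc: ~dl & ~dc, lambda dl, dc: dl),
    "TD_gt_DC+DLDC": (lambda dl, dc: ~dl & ~dc, lambda dl, dc: dc),
    "TD_gt_DL": (lambda dl, dc: ~dl & ~dc, lambda dl, dc: dl & ~dc),
    "TD_gt_DC": (lambda dl, dc: ~dl & ~dc, lambda dl, dc: ~dl & dc),
    "TD_gt_DLDC": (lambda dl, dc: ~dl & ~dc, lambda dl, dc: dl & dc),
}


@dataclass
class StatMap:
    """One voxelwise statistic map with matching p values."""

    effect_label: str
    stat_values: np.ndarray
    p_values: np.ndarray
    df: tuple
    stat_kind: str = "F"  # 'F' or 't'


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def voxelwise_factorial_anova(
    values: np.ndarray,
    dyslexia: np.ndarray,
    dyscalculia: np.ndarray,
    mask: np.ndarray | None = None,
    ss_type: int = 3,
) -> dict[str, StatMap]:
    """Per-voxel 2 x 2 factorial ANOVA plus directional group t maps.

    ``values`` is (n_subjects, ...grid); factorial effects use Type III sums
    of squares via effect-coded model comparison (Type I sequential available
    with ``ss_type=1``).  Directional maps are pooled-variance two-sample t
    statistics with one-sided (group1 > group2) p values, plus pairwise t
    maps among the three disorder groups.
    """
    dl = np.asarray(dyslexia, bool)
    dc = np.asarray(dyscalculia, bool)
    values = np.asarray(values, float)
    n = values.shape[0]
    if dl.shape[0] != n or dc.shape[0] != n:
        raise ValueError("flag arrays must match the number of subjects")
    grid_shape = values.shape[1:]
    if mask is None:
        mask = np.ones(grid_shape, bool)
    Y = values.reshape(n, -1)[:, mask.ravel()]
    a = np.where(dl, 1.0, -1.0)
    b = np.where(dc, 1.0, -1.0)
    cols = {"intercept": np.ones(n), "DL_main": a, "DC_main": b, "DLxDC": a * b}
    order = ["intercept", "DL_main", "DC_main", "DLxDC"]
    X_full = np.column_stack([cols[k] for k in order])
    cells = [(~dl & ~dc), (dl & ~dc), (~dl & dc), (dl & dc)]
    if ss_type not in (1, 3):
        raise ValueError(f"ss_type must be 1 or 3, got {ss_type}")
    interaction_ok = all(c.sum() >= 2 for c in cells)
    rss_full = _rss(X_full, Y)
    dof_err = n - X_full.shape[1]
    mse = rss_full / dof_err
    # relative scale for detecting an exactly-zero error stratum despite
    # floating-point cancellation (e.g. identical values within every cell)
    tiny = 1e-12 * np.maximum(np.einsum("ij,ij->j", Y, Y) / n, 1e-300)

    def _to_grid(flat: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(int(np.prod(grid_shape)), fill)
        out[mask.ravel()] = flat
        return out.reshape(grid_shape)

    maps: dict[str, StatMap] = {}
    for effect in FACTORIAL_EFFECTS:
        if effect == "DLxDC" and not interaction_ok:
            warnings.warn("interaction effect skipped: some factorial cell has fewer than 2 subjects")
            continue
        if ss_type == 3:
            X_red = np.column_stack([cols[k] for k in order if k != effect])
            ss_eff = _rss(X_red, Y) - rss_full
        else:  # sequential
            upto = order[: order.index(effect)]
            X_red = np.column_stack([cols[k] for k in upto]) if upto else np.zeros((n, 0))
            X_inc = np.column_stack([cols[k] for k in upto + [effect]])
            ss_eff = (_rss(X_red, Y) if upto else np.einsum("ij,ij->j", Y, Y)) - _rss(X_inc, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss_eff / mse
            F = np.where((mse < tiny) & (ss_eff > tiny), np.inf, F)
            F = np.where((mse < tiny) & (ss_eff <= tiny), 0.0, F)
        F = np.clip(F, 0.0, None)  # tiny negative values from float cancellation
        p = stats.f.sf(F, 1, dof_err)
        maps[effect] = StatMap(effect, _to_grid(F), _to_grid(p, 1.0), (1, dof_err), "F")

    for label, (sel1, sel2) in DIRECTIONAL_COMPARISONS.items():
        g1, g2 = sel1(dl, dc), sel2(dl, dc)
        if g1.sum() < 2 or g2.sum() < 2:
            warnings.warn(f"comparison {label} skipped: a group has fewer than 2 subjects")
            continue
        t, p, df = _two_sample_t(Y[g1], Y[g2])
        maps[label] = StatMap(label, _to_grid(t), _to_grid(p, 1.0), (df,), "t")

    # pairwise among the disorder groups (descriptive follow-ups)
    disorder = {"DL": dl & ~dc, "DC": ~dl & dc, "DLDC": dl & dc}
    for (n1, m1), (n2, m2) in [(a_, b_) for i, a_ in enumerate(disorder.items()) for b_ in list(disorder.items())[i + 1 :]]:
        label = f"{n1}_gt_{n2}"
        if m1.sum() < 2 or m2.sum() < 2:
            warnings.warn(f"comparison {label} skipped: a group has fewer than 2 subjects")
            continue
        t, p, df = _two_sample_t(Y[m1], Y[m2])
        maps[label] = StatMap(label, _to_grid(t), _to_grid(p, 1.0), (df,), "t")
    return maps


def _two_sample_t(Y1: np.ndarray, Y2: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled-variance two-sample t per voxel, one-sided p (group1 > group2)."""
    n1, n2 = Y1.shape[0], Y2.shape[0]
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * Y1.var(axis=0, ddof=1) + (n2 - 1) * Y2.var(axis=0, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (Y1.mean(axis=0) - Y2.mean(axis=0)) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    return t, stats.t.sf(t, df), df


@dataclass
class ThresholdResult:
    mask: np.ndarray
    method: str
    level: float
    n_suprathreshold: int = field(init=False)

    def __post_init__(self):
        self.n_suprathreshold = int(self.mask.sum())


def fdr_correct(p_values: np.ndarray, q: float = 0.05, mask: np.ndarray | None = None) -> ThresholdResult:
    """Benjamini-Hochberg step-up over all in-mask voxels."""
    p = np.asarray(p_values, float)
    if mask is None:
        mask = np.isfinite(p)
    else:
        mask = np.asarray(mask, bool) & np.isfinite(p)
    out = np.zeros(p.shape, bool)
    flat = p[mask]
    if flat.size:
        if np.any((flat < 0) | (flat > 1)):
            raise ValueError("p values must lie in [0, 1]")
        out[mask] = multipletests(flat, alpha=q, method="fdr_bh")[0]
    return ThresholdResult(mask=out, method="fdr", level=q)


def uncorrected_mask(p_values: np.ndarray, alpha: float = 0.001, mask: np.ndarray | None = None) -> ThresholdResult:
    """Elementwise strict threshold p < alpha within the analysis mask."""
    p = np.asarray(p_values, float)
    keep = np.isfinite(p) if mask is None else (np.asarray(mask, bool) & np.isfinite(p))
    return ThresholdResult(mask=(p < alpha) & keep, method="uncorrected", level=alpha)
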