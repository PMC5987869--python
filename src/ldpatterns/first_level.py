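"""First-level GLM analysis of block-design BOLD runs.

Per-subject contrast maps are produced by smoothing, building a boxcar design
matrix (one regressor per presentation format, convolved with a canonical
hemodynamic response), adding the six realignment parameters as nuisance
regressors, fitting an ordinary least-squares GLM per voxel, and combining
retained runs in a single concatenated model with per-run intercepts.

Fixation is the implicit baseline: it receives no regressor, so each format
beta is directly the format-versus-fixation contrast estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, ndimage

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # fwhm = sigma * 2*sqrt(2 ln 2)

#: temporal resolution (s) of the oversampled grid used for HRF convolution
_OVERSAMPLE_DT = 0.1


def smooth_volume(grid: np.ndarray, fwhm_mm: float, voxel_size_mm: float | tuple = 2.2) -> np.ndarray:
    """Isotropic Gaussian smoothing of a 3D volume or 4D (x, y, z, t) series.

    ``fwhm_mm = 0`` is the identity.  Boundaries are handled by reflection so
    constant fields are preserved exactly, including at the rim.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    vox = np.atleast_1d(np.asarray(voxel_size_mm, dtype=float))
    if vox.size == 1:
        vox = np.repeat(vox, 3)
    if np.any(vox <= 0):
        raise ValueError(f"voxel_size_mm must be positive, got {voxel_size_mm}")
    if fwhm_mm == 0:
        return np.asarray(grid, dtype=float).copy()
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / vox
    sigmas = list(sigma_vox)
    if grid.ndim == 4:
        sigmas = sigmas + [0.0]  # never smooth over time
    elif grid.ndim != 3:
        raise ValueError(f"expected a 3D or 4D grid, got ndim={grid.ndim}")
    return ndimage.gaussian_filter(np.asarray(grid, dtype=float), sigma=sigmas, mode="reflect")


def hrf_kernel(dt: float = _OVERSAMPLE_DT, kind: str | None = "glover") -> np.ndarray:
    """Hemodynamic response kernel sampled at resolution ``dt`` seconds.

    ``kind='glover'`` is the canonical double-gamma response (peak ~5 s,
    undershoot ~15 s), normalized to unit peak so a sustained block regressor
    plateaus at the underlying amplitude.  ``kind=None`` returns a unit
    impulse (no convolution), used for tests and for strictly boxcar designs.
    """
    if kind is None or kind == "none":
        return np.array([1.0])
    if kind != "glover":
        raise ValueError(f"unknown HRF kind {kind!r}")
    from nilearn.glm.first_level import glover_hrf

    h = glover_hrf(t_r=dt, oversampling=1, time_length=32.0)
    return h / h.max()


def condition_regressors(design, timing, hrf: str | None = "glover") -> tuple[np.ndarray, list[str]]:
    """Convolved block boxcar regressors for one run, sampled at scan onsets.

    Returns an ``(n_scans, n_formats)`` array (column order = ``timing.formats``)
    built from the run's 15 s format blocks.  The reference presentation at the
    start of each block is part of the block regressor, matching a model with
    boxcars spanning the full block length.
    """
    dt = _OVERSAMPLE_DT
    kernel = hrf_kernel(dt, hrf)
    total_s = design.n_scans * timing.tr_s
    n_fine = int(np.ceil(total_s / dt)) + kernel.size
    t_fine = np.arange(n_fine) * dt
    cols = []
    for fmt in timing.formats:
        box = np.zeros(n_fine)
        for onset, duration in design.block_spans(fmt):
            box[(t_fine >= onset) & (t_fine < onset + duration)] = 1.0
        conv = np.convolve(box, kernel)[:n_fine]
        scan_idx = np.round(np.arange(design.n_scans) * timing.tr_s / dt).astype(int)
        cols.append(conv[scan_idx])
    return np.column_stack(cols), list(timing.formats)


@dataclass
class DesignMatrix:
    """GLM design for one or several concatenated runs.

    ``matrix`` is ``n_scans_total x k``; ``labels`` names every column.  The
    first ``len(condition_labels)`` columns are the convolved format boxcars;
    the rest are per-run motion nuisance regressors and run intercepts.
    """

    matrix: np.ndarray
    labels: list[str]
    condition_labels: list[str]
    hrf_spec: str | None = "glover"

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def condition_index(self, label: str) -> int:
        try:
            return self.condition_labels.index(label)
        except ValueError:
            raise KeyError(f"no condition column {label!r}; have {self.condition_labels}") from None


def _check_rank(matrix: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        # locate offending columns via the pivoted QR diagonal
        _, r, piv = linalg.qr(matrix, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [labels[piv[i]] for i in range(matrix.shape[1]) if i >= rank or diag[i] < 1e-10 * diag[0]]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {matrix.shape[1]}); offending columns: {bad}")


def build_design_matrix(design, motion, timing, hrf: str | None = "glover") -> DesignMatrix:
    """Single-run design: format boxcars + 6 motion regressors + intercept."""
    params = np.asarray(motion.params, dtype=float)
    if params.shape[0] != design.n_scans:
        raise ValueError(f"motion trace has {params.shape[0]} scans but design has {design.n_scans}")
    conds, cond_labels = condition_regressors(design, timing, hrf)
    for j, lab in enumerate(cond_labels):
        if not np.any(conds[:, j]):
            warnings.warn(f"condition column {lab!r} is all zeros (no blocks of this format in the run)")
    motion_cols = params - params.mean(axis=0)
    intercept = np.ones((design.n_scans, 1))
    matrix = np.hstack([conds, motion_cols, intercept])
    labels = cond_labels + list(motion.AXES) + ["intercept"]
    # all-zero nuisance columns (e.g. a perfectly still axis) are harmless for
    # lstsq and excluded from the rank check; zero condition columns warn above
    nonzero = [j for j in range(matrix.shape[1]) if np.any(matrix[:, j])]
    _check_rank(matrix[:, nonzero], [labels[j] for j in nonzero])
    return DesignMatrix(matrix=matrix, labels=labels, condition_labels=cond_labels, hrf_spec=hrf)


def concatenate_designs(designs: list[DesignMatrix]) -> DesignMatrix:
    """Stack run designs: shared condition columns, per-run nuisance blocks."""
    if not designs:
        raise ValueError("need at least one run design")
    cond_labels = designs[0].condition_labels
    n_cond = len(cond_labels)
    n_total = sum(d.n_scans for d in designs)
    n_nuis = sum(d.matrix.shape[1] - n_cond for d in designs)
    matrix = np.zeros((n_total, n_cond + n_nuis))
    labels = list(cond_labels)
    row = 0
    col = n_cond
    for r, d in enumerate(designs):
        if d.condition_labels != cond_labels:
            raise ValueError("all runs must share condition columns")
        n = d.n_scans
        matrix[row : row + n, :n_cond] = d.matrix[:, :n_cond]
        k = d.matrix.shape[1] - n_cond
        matrix[row : row + n, col : col + k] = d.matrix[:, n_cond:]
        labels += [f"run{r}_{lab}" for lab in d.labels[n_cond:]]
        row += n
        col += k
    return DesignMatrix(matrix=matrix, labels=labels, condition_labels=cond_labels, hrf_spec=designs[0].hrf_spec)


@dataclass
class GLMFit:
    """Voxelwise OLS fit: per-column beta grids plus residual variance."""

    betas: np.ndarray  # (k, *grid)
    resid_var: np.ndarray  # (*grid,), RSS / dof
    dof: int
    design: DesignMatrix
    grid_shape: tuple

    def beta(self, label: str) -> np.ndarray:
        return self.betas[self.design.labels.index(label)]


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares per voxel.

    ``bold`` is ``(x, y, z, t)`` (or already ``(t, n_voxels)``).  Betas minimize
    the residual sum of squares; ``resid_var`` is RSS divided by the residual
    degrees of freedom ``n_scans - rank(X)``.
    """
    X = design.matrix
    if bold.ndim == 4:
        grid_shape = bold.shape[:3]
        Y = bold.reshape(-1, bold.shape[3]).T
    elif bold.ndim == 2:
        grid_shape = (bold.shape[1],)
        Y = bold
    else:
        raise ValueError(f"bold must be 4D or 2D, got ndim={bold.ndim}")
    if Y.shape[0] != X.shape[0]:
        raise ValueError(f"bold has {Y.shape[0]} scans but design has {X.shape[0]}")
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - int(rank)
    rss = np.einsum("ij,ij->j", resid, resid)
    resid_var = rss / dof if dof > 0 else np.full(rss.shape, np.nan)
    return GLMFit(
        betas=beta.reshape(X.shape[1], *grid_shape),
        resid_var=resid_var.reshape(grid_shape),
        dof=dof,
        design=design,
        grid_shape=grid_shape,
    )


@dataclass
class ContrastMap:
    """Per-subject format-versus-fixation contrast for one 3D grid."""

    values: np.ndarray
    t_values: np.ndarray
    dof: int
    subject_id: str = ""
    contrast_label: str = ""


def contrast_map(fit: GLMFit, contrast_label: str, subject_id: str = "") -> ContrastMap:
    """Contrast estimate and t map for one format column (fixation implicit)."""
    idx = fit.design.condition_index(contrast_label)
    X = fit.design.matrix
    xtx_inv = np.linalg.pinv(X.T @ X)
    c = np.zeros(X.shape[1])
    c[idx] = 1.0
    var_scale = float(c @ xtx_inv @ c)
    est = fit.betas[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(fit.resid_var * var_scale)
    return ContrastMap(values=est, t_values=t, dof=fit.dof, subject_id=subject_id, contrast_label=f"{contrast_label}-fix")


def fit_subject(
    runs: list[tuple[np.ndarray, object, object]],
    timing,
    hrf: str | None = "glover",
    fwhm_mm: float = 0.0,
    voxel_size_mm: float = 2.2,
    combine: str = "concat",
    subject_id: str = "",
) -> dict[str, ContrastMap]:
    """Smooth, fit, and contrast all retained runs of one subject.

    ``runs`` is a list of ``(bold_4d, RunDesign, MotionTrace)`` for the runs
    that survived motion QC.  ``combine='concat'`` fits one concatenated GLM
    with per-run intercepts and motion blocks; ``combine='average'`` averages
    per-run contrast estimates (t maps then come from the run-mean / SEM).
    """
    if not runs:
        raise ValueError("need at least one retained run")
    if combine not in ("concat", "average"):
        raise ValueError(f"combine must be 'concat' or 'average', got {combine!r}")
    designs = [build_design_matrix(d, m, timing, hrf) for _, d, m in runs]
    bolds = [smooth_volume(b, fwhm_mm, voxel_size_mm) if fwhm_mm > 0 else np.asarray(b, float) for b, _, _ in runs]
    if combine == "concat":
        design = concatenate_designs(designs)
        bold = np.concatenate(bolds, axis=-1)
        fit = fit_glm(bold, design)
        return {fmt: contrast_map(fit, fmt, subject_id) for fmt in timing.formats}
    per_run = [{fmt: contrast_map(fit_glm(b, d), fmt, subject_id) for fmt in timing.formats} for b, d in zip(bolds, designs)]
    out = {}
    for fmt in timing.formats:
        stack = np.stack([pr[fmt].values for pr in per_run])
        mean = stack.mean(axis=0)
        if stack.shape[0] > 1:
            sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / sem
            dof = stack.shape[0] - 1
        else:
            t = per_run[0][fmt].t_values
            dof = per_run[0][fmt].dof
        out[fmt] = ContrastMap(values=mean, t_values=t, dof=dof, subject_id=subject_id, contrast_label=f"{fmt}-fix")
    return out
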