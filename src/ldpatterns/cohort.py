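"""Synthetic cohort generator for a four-group arithmetic fMRI study.

Emulates the study design end to end so every analysis stage has a
ground-truth-bearing input: a block-design subtraction task (three
presentation formats -- dot arrays, Arabic digits, number words -- in 15 s
blocks alternating with 15 s fixation, four runs), four diagnostic groups
(typically developing, dyslexia, dyscalculia, comorbid; default sizes
22/14/8/8), per-voxel format amplitudes with a shared-versus-specific
disorder deviation structure, random-walk motion traces with optional
excessive-motion runs, AR(1) BOLD noise, and a behavioral trial table with
group-by-format effects.

The disorder deviation geometry is the simulator's main dial: the dyslexia
and dyscalculia group deviations from the typically developing mean pattern
are built from orthonormal voxel patterns ``s`` (shared), ``u_DL`` and
``u_DC`` (disorder-specific) as

    dev_DL = delta * (sqrt(rho) * s + sqrt(1 - rho) * u_DL)
    dev_DC = delta * (sqrt(rho) * s + sqrt(1 - rho) * u_DC)

so ``rho_shared`` is exactly the cosine between the two group deviations:
``rho_shared = 1`` makes the disorders deviate identically (the similarity
hypothesis), ``rho_shared = 0`` makes their deviations orthogonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import first_level

FORMATS = ("dots", "digits", "words")
#: run-wise reference magnitudes, cycled in this fixed order
REFERENCE_ORDER = (4, 5, 4, 5)
GROUP_NAMES = ("TD", "DL", "DC", "DLDC")

MOTION_AXES = ("x_mm", "y_mm", "z_mm", "pitch_rad", "roll_rad", "yaw_rad")


def group_name(dyslexia: bool, dyscalculia: bool) -> str:
    return {(False, False): "TD", (True, False): "DL", (False, True): "DC", (True, True): "DLDC"}[
        (bool(dyslexia), bool(dyscalculia))
    ]


# ---------------------------------------------------------------------------
# task timing and run design
# ---------------------------------------------------------------------------


@dataclass
class TimingParams:
    """Timing of the block-design subtraction task.

    A format block is one reference presentation (900 ms) followed by
    ``items_per_block`` trials of a 300 ms fixation plus a 4400 ms item:
    900 + 3 * (300 + 4400) ms = 15 s, equal to the fixation block length.
    """

    reference_ms: float = 900.0
    trial_fixation_ms: float = 300.0
    item_ms: float = 4400.0
    items_per_block: int = 3
    blocks_per_format: int = 4
    formats: tuple = FORMATS
    fixation_block_s: float = 15.0
    tr_s: float = 3.0
    n_runs: int = 4

    def __post_init__(self):
        for name in ("reference_ms", "trial_fixation_ms", "item_ms", "fixation_block_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("items_per_block", "blocks_per_format", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if len(self.formats) < 1:
            raise ValueError("formats must be non-empty")

    @property
    def format_block_s(self) -> float:
        """Format block duration implied by the event timings (seconds)."""
        return (self.reference_ms + self.items_per_block * (self.trial_fixation_ms + self.item_ms)) / 1000.0

    @property
    def trials_per_format_per_run(self) -> int:
        return self.items_per_block * self.blocks_per_format


@dataclass
class RunDesign:
    """Event layout of one run: alternating fixation and format blocks."""

    events: pd.DataFrame  # columns: onset_s, duration_s, condition
    blocks: pd.DataFrame  # columns: onset_s, duration_s, condition (block level)
    n_scans: int
    reference_magnitude: int

    def block_spans(self, condition: str) -> list[tuple[float, float]]:
        sel = self.blocks[self.blocks["condition"] == condition]
        return list(zip(sel["onset_s"], sel["duration_s"]))

    def trial_count(self, fmt: str) -> int:
        return int((self.events["condition"] == fmt).sum())


def _balanced_format_order(timing: TimingParams, rng: np.random.Generator) -> list[str]:
    """Format block order: each cycle of ``len(formats)`` blocks is a fresh
    permutation of the formats, so counts stay balanced throughout the run."""
    order: list[str] = []
    for _ in range(timing.blocks_per_format):
        order.extend(rng.permutation(list(timing.formats)))
    return order


def generate_run_design(timing: TimingParams, run_index: int, seed: int = 0) -> RunDesign:
    """Lay out one run of the task.

    Fixation and format blocks strictly alternate, starting and ending with
    fixation.  The format block order is a seeded balanced permutation.  The
    reference magnitude follows the fixed [4 5 4 5] cycle over runs.
    """
    if run_index < 0:
        raise ValueError(f"run_index must be >= 0, got {run_index}")
    rng = np.random.default_rng([seed, 1009, run_index])
    order = _balanced_format_order(timing, rng)
    block_len = timing.format_block_s
    ev_rows, blk_rows = [], []
    t = 0.0
    for fmt in order:
        blk_rows.append((t, timing.fixation_block_s, "fixation"))
        ev_rows.append((t, timing.fixation_block_s, "fixation"))
        t += timing.fixation_block_s
        blk_rows.append((t, block_len, fmt))
        ev_rows.append((t, timing.reference_ms / 1000.0, "reference"))
        item_t = t + timing.reference_ms / 1000.0
        for _ in range(timing.items_per_block):
            item_t += timing.trial_fixation_ms / 1000.0
            ev_rows.append((item_t, timing.item_ms / 1000.0, fmt))
            item_t += timing.item_ms / 1000.0
        t += block_len
    blk_rows.append((t, timing.fixation_block_s, "fixation"))
    ev_rows.append((t, timing.fixation_block_s, "fixation"))
    t += timing.fixation_block_s
    n_scans = int(math.ceil(t / timing.tr_s))
    events = pd.DataFrame(ev_rows, columns=["onset_s", "duration_s", "condition"])
    blocks = pd.DataFrame(blk_rows, columns=["onset_s", "duration_s", "condition"])
    return RunDesign(
        events=events,
        blocks=blocks,
        n_scans=n_scans,
        reference_magnitude=REFERENCE_ORDER[run_index % len(REFERENCE_ORDER)],
    )


# ---------------------------------------------------------------------------
# motion traces
# ---------------------------------------------------------------------------


@dataclass
class MotionTrace:
    """Per-run realignment parameters: n_scans x 6 (mm and radians)."""

    params: np.ndarray
    AXES = MOTION_AXES

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion params must be (n_scans, 6), got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion params must be finite")

    @property
    def n_scans(self) -> int:
        return self.params.shape[0]


def generate_motion_trace(
    n_scans: int,
    severity: float = 0.05,
    spike_spec: tuple | None = None,
    seed: int = 0,
    rotation_radius_mm: float = 50.0,
) -> MotionTrace:
    """Random-walk head motion with optional injected spikes.

    Translation steps have standard deviation ``severity`` mm; rotation steps
    ``severity / rotation_radius_mm`` rad, so their arc displacement on a
    sphere of that radius matches the translational scale.  ``spike_spec =
    (transition_index, axis, magnitude_mm, n_consecutive)`` adds a step of the
    given millimetre magnitude on ``n_consecutive`` consecutive transitions
    (rotation axes receive ``magnitude_mm / rotation_radius_mm`` radians).
    """
    if n_scans < 2:
        raise ValueError(f"n_scans must be >= 2, got {n_scans}")
    if severity < 0:
        raise ValueError(f"severity must be >= 0, got {severity}")
    rng = np.random.default_rng([seed, 2003])
    scales = np.array([severity] * 3 + [severity / rotation_radius_mm] * 3)
    steps = rng.normal(size=(n_scans - 1, 6)) * scales
    if spike_spec is not None:
        t0, axis, magnitude_mm, n_consec = spike_spec
        if isinstance(axis, str):
            axis = MOTION_AXES.index(axis)
        if not (0 <= t0 and t0 + n_consec <= n_scans - 1):
            raise ValueError(
                f"spike transitions [{t0}, {t0 + n_consec}) out of range for {n_scans - 1} transitions"
            )
        mag = magnitude_mm if axis < 3 else magnitude_mm / rotation_radius_mm
        steps[t0 : t0 + n_consec, axis] += mag
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(params=params)


# ---------------------------------------------------------------------------
# group structure and amplitude maps
# ---------------------------------------------------------------------------


@dataclass
class GroupStructure:
    """Cohort composition and the latent disorder-deviation geometry."""

    n_td: int = 22
    n_dl: int = 14
    n_dc: int = 8
    n_dldc: int = 8
    effect_size_delta: float = 8.0
    rho_shared: float = 0.5
    sigma_subject: float = 0.1
    sigma_noise: float = 1.0
    comorbid_rule: str = "additive"

    def __post_init__(self):
        for name in ("n_td", "n_dl", "n_dc", "n_dldc"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2 (leave-pair-out needs pairs), got {getattr(self, name)}")
        if not 0.0 <= self.rho_shared <= 1.0:
            raise ValueError(f"rho_shared must lie in [0, 1], got {self.rho_shared}")
        if self.sigma_subject < 0 or self.sigma_noise < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if self.effect_size_delta < 0:
            raise ValueError(f"effect_size_delta must be >= 0, got {self.effect_size_delta}")
        if self.comorbid_rule not in ("additive", "average"):
            raise ValueError(f"comorbid_rule must be 'additive' or 'average', got {self.comorbid_rule!r}")

    @property
    def n_total(self) -> int:
        return self.n_td + self.n_dl + self.n_dc + self.n_dldc

    def subject_flags(self) -> list[tuple[str, bool, bool]]:
        """(subject_id, dyslexia, dyscalculia) for every subject, TD first."""
        rows = []
        for g, (dl, dc), n in zip(
            GROUP_NAMES,
            [(False, False), (True, False), (False, True), (True, True)],
            [self.n_td, self.n_dl, self.n_dc, self.n_dldc],
        ):
            rows += [(f"sub-{g}{i + 1:02d}", dl, dc) for i in range(n)]
        return rows


def default_roi_labels(grid_shape: tuple = (16, 16, 16), margin: int = 2) -> tuple[np.ndarray, dict]:
    """Toy ROI parcellation: an inner 'brain' box split into four slabs.

    Label 0 is background; labels 1-4 are contiguous slabs along the first
    axis, standing in for lobe-scale anatomical masks.
    """
    labels = np.zeros(grid_shape, dtype=int)
    inner = tuple(slice(margin, s - margin) for s in grid_shape)
    nx = grid_shape[0] - 2 * margin
    if nx < 1:
        raise ValueError(f"grid too small for margin {margin}: {grid_shape}")
    all_names = ("frontal", "parietal", "temporal", "occipital")
    n_slabs = min(4, nx)
    bounds = np.linspace(margin, grid_shape[0] - margin, n_slabs + 1).astype(int)
    for k in range(n_slabs):
        sl = (slice(bounds[k], bounds[k + 1]),) + inner[1:]
        labels[sl] = k + 1
    names = {k + 1: all_names[k] for k in range(n_slabs)}
    return labels, names


@dataclass
class AmplitudeMap:
    """Latent per-format activation amplitudes for one subject."""

    grids: dict  # format -> 3D array
    roi_labels: np.ndarray
    roi_names: dict = field(default_factory=dict)

    def __post_init__(self):
        for fmt, g in self.grids.items():
            if g.shape != self.roi_labels.shape:
                raise ValueError(f"grid for {fmt!r} has shape {g.shape} != roi labels {self.roi_labels.shape}")


@dataclass
class AmplitudeTruth:
    """Exact group-level structure behind the per-subject amplitude maps."""

    mu: dict  # format -> 3D array (TD mean pattern)
    dev_dl: dict  # format -> 3D array
    dev_dc: dict
    dev_dldc: dict
    roi_labels: np.ndarray
    roi_names: dict

    def group_mean(self, fmt: str, dyslexia: bool, dyscalculia: bool) -> np.ndarray:
        out = self.mu[fmt].copy()
        if dyslexia and dyscalculia:
            out += self.dev_dldc[fmt]
        elif dyslexia:
            out += self.dev_dl[fmt]
        elif dyscalculia:
            out += self.dev_dc[fmt]
        return out


def generate_amplitude_maps(
    structure: GroupStructure,
    grid_shape: tuple = (16, 16, 16),
    roi_spec: tuple | None = None,
    seed: int = 0,
    formats: tuple = FORMATS,
    mu_scale: float = 1.0,
    mu_offset: float = 1.0,
) -> tuple[list, dict, AmplitudeTruth]:
    """Draw per-subject amplitude maps with the shared/specific deviation geometry.

    Returns ``(subject_flags, {subject_id: AmplitudeMap}, AmplitudeTruth)``.
    Within the in-brain mask, subject ``i`` of group ``g`` gets, per format,

        A_i = mu + z_DL(g) * dev_DL + z_DC(g) * dev_DC + N(0, sigma_subject^2)

    with ``z`` indicators 0/1 (the comorbid group follows ``comorbid_rule``:
    additive ``dev_DL + dev_DC`` or their average).  ``dev_DL`` and ``dev_DC``
    are unit-norm patterns scaled by ``effect_size_delta`` whose cosine equals
    ``rho_shared`` exactly, by construction from three orthonormal patterns.
    """
    if roi_spec is None:
        roi_labels, roi_names = default_roi_labels(grid_shape)
    else:
        roi_labels, roi_names = roi_spec
        if roi_labels.shape != tuple(grid_shape):
            raise ValueError(f"roi labels shape {roi_labels.shape} != grid_shape {tuple(grid_shape)}")
    mask = roi_labels > 0
    V = int(mask.sum())
    if V < 4:
        raise ValueError(f"in-brain mask has only {V} voxels; need >= 4")
    rng = np.random.default_rng([seed, 3001])
    delta, rho = structure.effect_size_delta, structure.rho_shared

    def to_grid(vec: np.ndarray) -> np.ndarray:
        g = np.zeros(grid_shape)
        g[mask] = vec
        return g

    mu, dev_dl, dev_dc, dev_dldc = {}, {}, {}, {}
    dev_vecs = {}
    for fmt in formats:
        mu_vec = mu_offset + mu_scale * rng.normal(size=V)
        basis, _ = np.linalg.qr(rng.normal(size=(V, 3)))
        s, u_dl, u_dc = basis.T
        d_dl = delta * (math.sqrt(rho) * s + math.sqrt(1.0 - rho) * u_dl)
        d_dc = delta * (math.sqrt(rho) * s + math.sqrt(1.0 - rho) * u_dc)
        d_dldc = d_dl + d_dc if structure.comorbid_rule == "additive" else 0.5 * (d_dl + d_dc)
        mu[fmt], dev_dl[fmt], dev_dc[fmt], dev_dldc[fmt] = map(to_grid, (mu_vec, d_dl, d_dc, d_dldc))
        dev_vecs[fmt] = (mu_vec, d_dl, d_dc, d_dldc)

    flags = structure.subject_flags()
    amplitude_maps = {}
    for sid, dl, dc in flags:
        grids = {}
        for fmt in formats:
            mu_vec, d_dl, d_dc, d_dldc = dev_vecs[fmt]
            vec = mu_vec.copy()
            if dl and dc:
                vec += d_dldc
            elif dl:
                vec += d_dl
            elif dc:
                vec += d_dc
            vec += structure.sigma_subject * rng.normal(size=V)
            grids[fmt] = to_grid(vec)
        amplitude_maps[sid] = AmplitudeMap(grids=grids, roi_labels=roi_labels, roi_names=roi_names)
    truth = AmplitudeTruth(mu=mu, dev_dl=dev_dl, dev_dc=dev_dc, dev_dldc=dev_dldc, roi_labels=roi_labels, roi_names=roi_names)
    return flags, amplitude_maps, truth


# ---------------------------------------------------------------------------
# BOLD forward model
# ---------------------------------------------------------------------------


def synthesize_bold(
    amplitude: AmplitudeMap,
    design: RunDesign,
    motion: MotionTrace,
    timing: TimingParams,
    noise: tuple[float, float] = (0.3, 1.0),
    motion_coupling: float = 0.0,
    seed: int = 0,
    baseline: float = 100.0,
    hrf: str | None = "glover",
) -> np.ndarray:
    """Forward model for one run: ``(x, y, z, t)`` BOLD array.

    Voxel time series = baseline + sum_f amplitude_v(f) * x_f(t)
    + motion_coupling * (standardized motion mix) + AR(1) noise, with the
    format regressors ``x_f`` built by the same routine the first-level GLM
    uses, so a noiseless run is exactly identifiable.
    """
    ar1, sigma = noise
    if not -1.0 < ar1 < 1.0:
        raise ValueError(f"ar1 coefficient must lie in (-1, 1), got {ar1}")
    if sigma < 0:
        raise ValueError(f"noise sigma must be >= 0, got {sigma}")
    if motion.n_scans != design.n_scans:
        raise ValueError(f"motion trace has {motion.n_scans} scans but design has {design.n_scans}")
    regs, fmt_labels = first_level.condition_regressors(design, timing, hrf)
    grid_shape = amplitude.roi_labels.shape
    amps = np.stack([amplitude.grids[f] for f in fmt_labels], axis=-1)  # (*grid, F)
    signal = amps @ regs.T  # (*grid, t)
    bold = baseline + signal
    if motion_coupling != 0.0:
        p = motion.params - motion.params.mean(axis=0)
        sd = p.std(axis=0)
        sd[sd == 0] = 1.0
        mix = (p / sd).sum(axis=1)
        bold = bold + motion_coupling * mix
    if sigma > 0:
        rng = np.random.default_rng([seed, 4001])
        n_t = design.n_scans
        eps = rng.normal(size=grid_shape + (n_t,)) * sigma
        noise_ts = np.empty_like(eps)
        # stationary AR(1): n_0 ~ N(0, sigma^2 / (1 - ar1^2))
        noise_ts[..., 0] = eps[..., 0] / math.sqrt(1.0 - ar1 * ar1) if ar1 != 0 else eps[..., 0]
        for t in range(1, n_t):
            noise_ts[..., t] = ar1 * noise_ts[..., t - 1] + eps[..., t]
        bold = bold + noise_ts
    return bold


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

#: per-group, per-format (accuracy, mean RT seconds, non-response probability).
#: The defaults encode the study-style direction of effects: dyscalculia
#: (DC + DLDC) hurts accuracy and raises non-response most strongly for dot
#: arrays; dyslexia hurts the symbolic formats; every disorder group responds
#: more slowly than TD, with under-additive comorbid slowing; non-response is
#: highest for dots, then digits, then words.
DEFAULT_BEHAVIOR_EFFECTS = {
    "TD": {"dots": (0.82, 2.45, 0.08), "digits": (0.92, 2.10, 0.05), "words": (0.91, 2.25, 0.03)},
    "DL": {"dots": (0.83, 2.80, 0.09), "digits": (0.86, 2.55, 0.10), "words": (0.83, 2.75, 0.08)},
    "DC": {"dots": (0.55, 3.00, 0.33), "digits": (0.83, 2.65, 0.12), "words": (0.82, 2.80, 0.09)},
    "DLDC": {"dots": (0.60, 2.90, 0.28), "digits": (0.80, 2.60, 0.14), "words": (0.78, 2.75, 0.11)},
}


def generate_behavior(
    structure: GroupStructure,
    effects_config: dict | None = None,
    seed: int = 0,
    timing: TimingParams | None = None,
    rt_sd: float = 0.5,
) -> pd.DataFrame:
    """Trial-level behavioral table with group-by-format effects.

    One row per subject x format x trial with ``correct`` in {0, 1, NaN} and
    ``rt_s`` (NaN iff non-response).  RTs are normal draws truncated to
    (0, item duration]; non-response trials carry no accuracy or RT.
    """
    if effects_config is None:
        effects_config = DEFAULT_BEHAVIOR_EFFECTS
    timing = timing or TimingParams()
    for g, fmts in effects_config.items():
        for fmt, (acc, rt, pnr) in fmts.items():
            if not (0.0 <= acc <= 1.0 and 0.0 <= pnr <= 1.0):
                raise ValueError(f"probabilities for {g}/{fmt} must lie in [0, 1], got acc={acc}, p_nr={pnr}")
            if rt <= 0:
                raise ValueError(f"mean RT for {g}/{fmt} must be positive, got {rt}")
    rt_max = timing.item_ms / 1000.0
    n_trials = timing.n_runs * timing.trials_per_format_per_run
    rng = np.random.default_rng([seed, 5003])
    rows = []
    for sid, dl, dc in structure.subject_flags():
        g = group_name(dl, dc)
        for fmt in timing.formats:
            acc, rt_mean, p_nr = effects_config[g][fmt]
            nr = rng.random(n_trials) < p_nr
            correct = (rng.random(n_trials) < acc).astype(float)
            rt = np.clip(rng.normal(rt_mean, rt_sd, n_trials), 0.05, rt_max)
            correct[nr] = np.nan
            rt[nr] = np.nan
            for k in range(n_trials):
                rows.append((sid, dl, dc, fmt, k, correct[k], rt[k]))
    return pd.DataFrame(
        rows, columns=["subject_id", "dyslexia", "dyscalculia", "format", "trial_index", "correct", "rt_s"]
    )


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    subject_id: str
    dyslexia: bool
    dyscalculia: bool
    amplitude: AmplitudeMap
    motion: list  # MotionTrace per run

    @property
    def group(self) -> str:
        return group_name(self.dyslexia, self.dyscalculia)


@dataclass
class Cohort:
    """A complete synthetic study dataset.

    BOLD runs are synthesized on demand (``synthesize_run``) rather than held
    in memory; everything is reproducible from ``seed``.
    """

    structure: GroupStructure
    timing: TimingParams
    subjects: list  # of SubjectRecord
    designs: list  # RunDesign per run, shared across subjects
    truth: AmplitudeTruth
    behavior: pd.DataFrame
    seed: int
    noise: tuple = (0.3, 1.0)
    motion_coupling: float = 0.0
    hrf: str | None = "glover"

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def synthesize_run(self, subject_index: int, run_index: int) -> np.ndarray:
        sub = self.subjects[subject_index]
        return synthesize_bold(
            sub.amplitude,
            self.designs[run_index],
            sub.motion[run_index],
            self.timing,
            noise=(self.noise[0], self.structure.sigma_noise),
            motion_coupling=self.motion_coupling,
            seed=int(np.random.default_rng([self.seed, 6007, subject_index, run_index]).integers(2**31)),
            hrf=self.hrf,
        )

    @property
    def flags(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.subject_id, s.dyslexia, s.dyscalculia, s.group) for s in self.subjects],
            columns=["subject_id", "dyslexia", "dyscalculia", "group"],
        )


def simulate_cohort(
    structure: GroupStructure | None = None,
    timing: TimingParams | None = None,
    grid_shape: tuple = (16, 16, 16),
    roi_spec: tuple | None = None,
    seed: int = 0,
    motion_severity: float = 0.05,
    p_bad_run: float = 0.1,
    bad_run_magnitude_mm: float = 3.0,
    ar1_coef: float = 0.3,
    motion_coupling: float = 0.0,
    behavior_effects: dict | None = None,
    hrf: str | None = "glover",
) -> Cohort:
    """Generate a full synthetic cohort in the study's design.

    ``p_bad_run`` is the probability that a run receives an excessive-motion
    spike (two consecutive >2.2 mm steps) and should be caught by motion QC;
    the study itself lost about 10% of runs to motion.
    """
    structure = structure or GroupStructure()
    timing = timing or TimingParams()
    designs = [generate_run_design(timing, r, seed=seed) for r in range(timing.n_runs)]
    flags, amplitude_maps, truth = generate_amplitude_maps(structure, grid_shape, roi_spec, seed=seed)
    rng = np.random.default_rng([seed, 7001])
    subjects = []
    for sid, dl, dc in flags:
        traces = []
        for r, design in enumerate(designs):
            spike = None
            if rng.random() < p_bad_run:
                t0 = int(rng.integers(0, design.n_scans - 3))
                axis = int(rng.integers(0, 3))
                spike = (t0, axis, bad_run_magnitude_mm, 2)
            traces.append(
                generate_motion_trace(
                    design.n_scans,
                    severity=motion_severity,
                    spike_spec=spike,
                    seed=int(rng.integers(2**31)),
                )
            )
        subjects.append(SubjectRecord(sid, dl, dc, amplitude_maps[sid], traces))
    behavior = generate_behavior(structure, behavior_effects, seed=seed, timing=timing)
    return Cohort(
        structure=structure,
        timing=timing,
        subjects=subjects,
        designs=designs,
        truth=truth,
        behavior=behavior,
        seed=seed,
        noise=(ar1_coef, structure.sigma_noise),
        motion_coupling=motion_coupling,
        hrf=hrf,
    )
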