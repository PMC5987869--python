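"""Head-motion quality control: run and subject exclusion rules.

Two run-level criteria operate on scan-to-scan displacements derived from the
six realignment parameters (rotations converted to arc length on a 50 mm
sphere, the usual framewise-displacement convention):

* axis rule -- a single axis moves more than one voxel size on a number of
  consecutive scan-to-scan transitions (default 2);
* Euclidean rule -- the Euclidean norm over all six displacement components
  exceeds one voxel size on any transition.

Both thresholds are strict ("more than"), so a displacement exactly equal to
the voxel size never triggers exclusion.  Subjects keeping fewer than half of
their runs are excluded entirely; exactly half counts as retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class QCThresholds:
    voxel_size_mm: float = 2.2
    n_consecutive: int = 2
    min_run_fraction: float = 0.5
    rotation_radius_mm: float = 50.0
    #: apply the rules to rotation axes too (as arc lengths); if False,
    #: translations only
    include_rotations: bool = True
    #: 'transitions' reads the consecutive-scan rule as the same axis
    #: exceeding threshold on n_consecutive consecutive transitions;
    #: 'span' reads it as a single displacement between scans t and
    #: t + n_consecutive
    consecutive_mode: str = "transitions"

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if not 0.0 < self.min_run_fraction <= 1.0:
            raise ValueError(f"min_run_fraction must lie in (0, 1], got {self.min_run_fraction}")
        if self.n_consecutive < 1:
            raise ValueError(f"n_consecutive must be >= 1, got {self.n_consecutive}")
        if self.consecutive_mode not in ("transitions", "span"):
            raise ValueError(f"consecutive_mode must be 'transitions' or 'span', got {self.consecutive_mode!r}")


def scan_to_scan_displacement(trace, radius: float = 50.0) -> np.ndarray:
    """Absolute per-axis displacement for every scan-to-scan transition.

    Returns ``(n_scans - 1, 6)``; rotation deltas are multiplied by ``radius``
    so every column is in millimetres.
    """
    params = np.asarray(trace.params if hasattr(trace, "params") else trace, dtype=float)
    if params.shape[0] < 2:
        raise ValueError(f"trace must have >= 2 scans, got {params.shape[0]}")
    deltas = np.abs(np.diff(params, axis=0))
    deltas[:, 3:] *= radius
    return deltas


def euclidean_motion(trace, radius: float = 50.0) -> np.ndarray:
    """Per-transition Euclidean norm over the six displacement components."""
    return np.linalg.norm(scan_to_scan_displacement(trace, radius), axis=1)


def _axis_rule_hits(deltas: np.ndarray, thresholds: QCThresholds) -> bool:
    over = deltas > thresholds.voxel_size_mm
    n = thresholds.n_consecutive
    if over.shape[0] < n:
        return False
    # any axis exceeding on n consecutive transitions
    run = np.ones(over.shape, dtype=bool)[: over.shape[0] - n + 1]
    for k in range(n):
        run &= over[k : over.shape[0] - n + 1 + k]
    return bool(run.any())


def _axis_rule_span(params: np.ndarray, thresholds: QCThresholds) -> bool:
    n = thresholds.n_consecutive
    if params.shape[0] <= n:
        return False
    disp = np.abs(params[n:] - params[:-n])
    disp[:, 3:] *= thresholds.rotation_radius_mm
    cols = slice(None) if thresholds.include_rotations else slice(0, 3)
    return bool((disp[:, cols] > thresholds.voxel_size_mm).any())


def evaluate_run(trace, thresholds: QCThresholds) -> dict:
    """Apply both exclusion rules to one run's motion trace."""
    deltas = scan_to_scan_displacement(trace, thresholds.rotation_radius_mm)
    cols = slice(None) if thresholds.include_rotations else slice(0, 3)
    axis_deltas = deltas[:, cols]
    if thresholds.consecutive_mode == "transitions":
        axis_hit = _axis_rule_hits(axis_deltas, thresholds)
    else:
        params = np.asarray(trace.params if hasattr(trace, "params") else trace, dtype=float)
        axis_hit = _axis_rule_span(params, thresholds)
    eucl = np.linalg.norm(deltas[:, cols], axis=1)
    eucl_hit = bool((eucl > thresholds.voxel_size_mm).any())
    reasons = [r for r, hit in [("axis_rule", axis_hit), ("euclidean_rule", eucl_hit)] if hit]
    return {
        "excluded": bool(reasons),
        "reasons": reasons,
        "max_axis_disp_mm": float(axis_deltas.max()),
        "max_euclidean_mm": float(eucl.max()),
        "mean_euclidean_mm": float(eucl.mean()),
        "cumulative_euclidean_mm": float(eucl.sum()),
    }


def exclude_runs(traces: dict, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Run-level QC over ``{subject_id: [MotionTrace per run]}``.

    Returns one row per run with exclusion flag, triggered rules, and motion
    summaries used downstream for the group comparison.
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    for sid, runs in traces.items():
        for r, trace in enumerate(runs):
            rec = evaluate_run(trace, thresholds)
            rows.append({"subject_id": sid, "run_index": r, **rec, "reasons": ",".join(rec["reasons"])})
    return pd.DataFrame(rows)


def exclude_subjects(run_report: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Subject-level QC: excluded iff retained-run fraction < min_run_fraction."""
    thresholds = thresholds or QCThresholds()
    if run_report.empty:
        raise ValueError("run report is empty")
    grp = run_report.groupby("subject_id", sort=False)
    out = grp.agg(
        n_runs=("run_index", "size"),
        runs_retained=("excluded", lambda e: int((~e).sum())),
    ).reset_index()
    out["retained_fraction"] = out["runs_retained"] / out["n_runs"]
    out["subject_excluded"] = out["retained_fraction"] < thresholds.min_run_fraction
    return out


@dataclass
class QCReport:
    """Combined run- and subject-level motion QC outcome."""

    runs: pd.DataFrame
    subjects: pd.DataFrame
    thresholds: QCThresholds

    @property
    def retained_subjects(self) -> list[str]:
        keep = self.subjects[~self.subjects["subject_excluded"]]
        return list(keep["subject_id"])

    def retained_runs(self, subject_id: str) -> list[int]:
        sel = self.runs[(self.runs["subject_id"] == subject_id) & (~self.runs["excluded"])]
        return list(sel["run_index"])


def run_qc(traces: dict, thresholds: QCThresholds | None = None) -> QCReport:
    thresholds = thresholds or QCThresholds()
    runs = exclude_runs(traces, thresholds)
    subjects = exclude_subjects(runs, thresholds)
    return QCReport(runs=runs, subjects=subjects, thresholds=thresholds)


def compare_group_motion(report: QCReport, flags: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA of residual motion across the four groups.

    After exclusion, compares per-subject mean scan-to-scan Euclidean motion,
    cumulative motion over retained runs, and the retained-run count, each
    with a 4-group one-way F test.  ``flags`` maps subject_id to group.
    """
    kept = report.runs[~report.runs["excluded"]]
    per_sub = kept.groupby("subject_id", sort=False).agg(
        mean_motion=("mean_euclidean_mm", "mean"),
        cumulative_motion=("cumulative_euclidean_mm", "mean"),
        runs_retained=("run_index", "size"),
    )
    retained = [s for s in report.retained_subjects if s in per_sub.index]
    per_sub = per_sub.loc[retained].join(flags.set_index("subject_id")["group"], how="left")
    counts = per_sub["group"].value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with fewer than 2 retained subjects: {dict(small)}")
    rows = []
    for measure in ("mean_motion", "cumulative_motion", "runs_retained"):
        samples = [per_sub.loc[per_sub["group"] == g, measure].to_numpy(float) for g in counts.index]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(*samples)
        if np.isnan(f):  # 0/0: identical values everywhere, no effect
            f, p = 0.0, 1.0
        rows.append(
            {
                "measure": measure,
                "F": float(f),
                "df_num": len(samples) - 1,
                "df_den": int(sum(len(s) for s in samples) - len(samples)),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
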