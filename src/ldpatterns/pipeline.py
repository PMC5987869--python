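"""End-to-end pipeline: simulate -> qc -> first-level -> group -> mvpa -> behavior.

Each stage reads its inputs from the output directory (standard on-disk
formats: 4D BOLD NIfTI, BIDS-style events TSV, 6-column motion TSV,
behavioral TSV), writes its outputs there, and records a manifest with
checksums.  A single global seed deterministically derives per-stage
substreams, so disabling one stage never shifts another stage's randomness.
Completed stages are skipped on re-run when their config section and seed
are unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import cohort as cohort_mod
from . import first_level as fl
from . import group_stats, motion_qc, mvpa
from .config import PipelineConfig

log = logging.getLogger("ldpatterns")

STAGE_ORDER = ("simulate", "qc", "first_level", "group", "mvpa", "behavior")
#: voxel geometry of the simulated grids (mm, isotropic)
VOXEL_MM = 2.2


def _affine() -> np.ndarray:
    return np.diag([VOXEL_MM, VOXEL_MM, VOXEL_MM, 1.0])


def _save_nifti(arr: np.ndarray, path: Path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), _affine()), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_rng_seed(seed: int, stage: str) -> int:
    h = int(hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest(), 16)
    return h % (2**31)


class PipelineRunner:
    """Executes pipeline stages against one output directory."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cohort_cache = None

    # -- bookkeeping --------------------------------------------------------

    def _stage_hash(self, stage: str) -> str:
        sect = getattr(self.config, stage if stage != "first_level" else "first_level", None)
        payload = {"seed": self.config.seed, "section": sect.model_dump(mode="json") if sect else {}}
        if stage in ("qc", "first_level", "group", "mvpa", "behavior"):
            payload["cohort"] = self.config.cohort.model_dump(mode="json")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def _done_path(self, stage: str) -> Path:
        return self.out / f".{stage}.done.json"

    def _is_done(self, stage: str) -> bool:
        p = self._done_path(stage)
        if not p.exists():
            return False
        try:
            rec = json.loads(p.read_text())
        except json.JSONDecodeError:
            return False
        return rec.get("hash") == self._stage_hash(stage) and all(
            (self.out / f).exists() for f in rec.get("outputs", [])
        )

    def _mark_done(self, stage: str, outputs: list[str]) -> dict:
        rec = {
            "stage": stage,
            "hash": self._stage_hash(stage),
            "outputs": outputs,
            "checksums": {f: _checksum(self.out / f) for f in outputs if (self.out / f).is_file()},
        }
        self._done_path(stage).write_text(json.dumps(rec, indent=1))
        return rec

    # -- shared inputs ------------------------------------------------------

    def _cohort(self) -> cohort_mod.Cohort:
        if self._cohort_cache is None:
            c = self.config.cohort
            structure = cohort_mod.GroupStructure(
                n_td=c.n_td,
                n_dl=c.n_dl,
                n_dc=c.n_dc,
                n_dldc=c.n_dldc,
                effect_size_delta=c.effect_size_delta,
                rho_shared=c.rho_shared,
                sigma_subject=c.sigma_subject,
                sigma_noise=c.sigma_noise,
                comorbid_rule=c.comorbid_rule,
            )
            self._cohort_cache = cohort_mod.simulate_cohort(
                structure,
                grid_shape=tuple(c.grid_shape),
                seed=_stage_rng_seed(self.config.seed, "simulate"),
                motion_severity=c.motion_severity,
                p_bad_run=c.p_bad_run,
                ar1_coef=c.ar1_coef,
                motion_coupling=c.motion_coupling,
                hrf=c.hrf,
            )
        return self._cohort_cache

    # -- stages -------------------------------------------------------------

    def stage_simulate(self) -> list[str]:
        coh = self._cohort()
        outputs = []
        (self.out / "bold").mkdir(exist_ok=True)
        for r, design in enumerate(coh.designs):
            p = self.out / f"events_run-{r}.tsv"
            ev = design.events.rename(columns={"onset_s": "onset", "duration_s": "duration", "condition": "trial_type"})
            ev.to_csv(p, sep="\t", index=False)
            outputs.append(p.name)
        _save_nifti(coh.truth.roi_labels, self.out / "roi_labels.nii", dtype=np.int16)
        outputs.append("roi_labels.nii")
        for fmt in coh.timing.formats:
            p = self.out / f"truth_mu_{fmt}.nii"
            _save_nifti(coh.truth.mu[fmt], p)
            outputs.append(p.name)
        for i, sub in enumerate(coh.subjects):
            for r in range(coh.timing.n_runs):
                mp = self.out / "bold" / f"{sub.subject_id}_run-{r}_motion.tsv"
                pd.DataFrame(sub.motion[r].params, columns=list(cohort_mod.MOTION_AXES)).to_csv(mp, sep="\t", index=False)
                outputs.append(str(mp.relative_to(self.out)))
                if self.config.cohort.write_bold:
                    bp = self.out / "bold" / f"{sub.subject_id}_run-{r}_bold.nii"
                    _save_nifti(coh.synthesize_run(i, r), bp)
                    outputs.append(str(bp.relative_to(self.out)))
        coh.behavior.to_csv(self.out / "behavior.tsv", sep="\t", index=False)
        outputs.append("behavior.tsv")
        coh.flags.to_csv(self.out / "participants.tsv", sep="\t", index=False)
        outputs.append("participants.tsv")
        manifest = {
            "seed": self.config.seed,
            "n_subjects": len(coh.subjects),
            "groups": coh.flags["group"].value_counts().to_dict(),
            "n_runs": coh.timing.n_runs,
            "grid_shape": list(self.config.cohort.grid_shape),
            "roi_names": coh.truth.roi_names,
        }
        (self.out / "cohort_manifest.json").write_text(json.dumps(manifest, indent=1))
        outputs.append("cohort_manifest.json")
        return outputs

    def stage_qc(self) -> list[str]:
        flags = pd.read_csv(self.out / "participants.tsv", sep="\t")
        thresholds = motion_qc.QCThresholds(
            voxel_size_mm=self.config.qc.voxel_size_mm,
            n_consecutive=self.config.qc.n_consecutive,
            min_run_fraction=self.config.qc.min_run_fraction,
            rotation_radius_mm=self.config.qc.rotation_radius_mm,
            include_rotations=self.config.qc.include_rotations,
        )
        traces = {}
        for sid in flags["subject_id"]:
            runs = sorted((self.out / "bold").glob(f"{sid}_run-*_motion.tsv"))
            traces[sid] = [
                cohort_mod.MotionTrace(pd.read_csv(p, sep="\t").to_numpy(float)) for p in runs
            ]
        report = motion_qc.run_qc(traces, thresholds)
        report.runs.to_csv(self.out / "qc_runs.tsv", sep="\t", index=False)
        report.subjects.to_csv(self.out / "qc_subjects.tsv", sep="\t", index=False)
        try:
            anova = motion_qc.compare_group_motion(report, flags)
            anova.to_csv(self.out / "qc_group_motion.tsv", sep="\t", index=False)
        except ValueError as e:
            log.warning("group motion comparison skipped: %s", e)
            anova = None
        summary = {
            "n_subjects": int(len(report.subjects)),
            "n_subjects_excluded": int(report.subjects["subject_excluded"].sum()),
            "n_runs_excluded": int(report.runs["excluded"].sum()),
            "pct_runs_excluded": float(100.0 * report.runs["excluded"].mean()),
        }
        (self.out / "qc_summary.json").write_text(json.dumps(summary, indent=1))
        out = ["qc_runs.tsv", "qc_subjects.tsv", "qc_summary.json"]
        if anova is not None:
            out.append("qc_group_motion.tsv")
        return out

    def stage_first_level(self) -> list[str]:
        coh = self._cohort()
        qc_runs = pd.read_csv(self.out / "qc_runs.tsv", sep="\t")
        qc_subjects = pd.read_csv(self.out / "qc_subjects.tsv", sep="\t")
        retained = set(qc_subjects.loc[~qc_subjects["subject_excluded"], "subject_id"])
        flc = self.config.first_level
        (self.out / "contrasts").mkdir(exist_ok=True)
        outputs = []
        for i, sub in enumerate(coh.subjects):
            if sub.subject_id not in retained:
                continue
            keep = qc_runs[(qc_runs["subject_id"] == sub.subject_id) & (~qc_runs["excluded"])]["run_index"]
            runs = []
            for r in sorted(keep):
                bp = self.out / "bold" / f"{sub.subject_id}_run-{r}_bold.nii"
                bold = _load_nifti(bp) if bp.exists() else coh.synthesize_run(i, r)
                runs.append((bold, coh.designs[r], sub.motion[r]))
            maps = fl.fit_subject(
                runs,
                coh.timing,
                hrf=flc.hrf,
                fwhm_mm=flc.fwhm_mm,
                voxel_size_mm=flc.voxel_size_mm,
                combine=flc.combine,
                subject_id=sub.subject_id,
            )
            for fmt, cm in maps.items():
                cp = self.out / "contrasts" / f"{sub.subject_id}_{fmt}_con.nii"
                tp = self.out / "contrasts" / f"{sub.subject_id}_{fmt}_t.nii"
                _save_nifti(cm.values, cp)
                _save_nifti(cm.t_values, tp)
                outputs += [str(cp.relative_to(self.out)), str(tp.relative_to(self.out))]
        return outputs

    def _load_contrasts(self) -> tuple[pd.DataFrame, dict]:
        flags = pd.read_csv(self.out / "participants.tsv", sep="\t")
        qc_subjects = pd.read_csv(self.out / "qc_subjects.tsv", sep="\t")
        retained = [s for s in flags["subject_id"] if s in set(qc_subjects.loc[~qc_subjects["subject_excluded"], "subject_id"])]
        flags = flags[flags["subject_id"].isin(retained)].reset_index(drop=True)
        maps = {}
        for fmt in ("dots", "digits", "words"):
            maps[fmt] = {
                sid: _load_nifti(self.out / "contrasts" / f"{sid}_{fmt}_con.nii") for sid in flags["subject_id"]
            }
        return flags, maps

    def stage_group(self) -> list[str]:
        flags, maps = self._load_contrasts()
        roi_labels = _load_nifti(self.out / "roi_labels.nii").astype(int)
        mask = roi_labels > 0
        gc = self.config.group
        outputs = []
        rows = []
        for fmt, submaps in maps.items():
            values = np.stack([submaps[s] for s in flags["subject_id"]])
            stat_maps = group_stats.voxelwise_factorial_anova(
                values, flags["dyslexia"].to_numpy(bool), flags["dyscalculia"].to_numpy(bool), mask=mask, ss_type=gc.ss_type
            )
            for label, sm in stat_maps.items():
                safe = label.replace(">", "gt")
                sp = self.out / f"group_{fmt}_{safe}_{sm.stat_kind}.nii"
                pp = self.out / f"group_{fmt}_{safe}_p.nii"
                _save_nifti(np.nan_to_num(sm.stat_values), sp)
                _save_nifti(np.nan_to_num(sm.p_values, nan=1.0), pp)
                outputs += [sp.name, pp.name]
                fdr = group_stats.fdr_correct(sm.p_values, q=gc.q_fdr, mask=mask)
                unc = group_stats.uncorrected_mask(sm.p_values, alpha=gc.alpha_uncorrected, mask=mask)
                rows.append((fmt, label, sm.stat_kind, fdr.n_suprathreshold, unc.n_suprathreshold, int(mask.sum())))
        summary = pd.DataFrame(
            rows, columns=["contrast", "effect", "stat", "n_fdr", "n_uncorrected", "n_in_mask"]
        )
        summary.to_csv(self.out / "group_thresholds.tsv", sep="\t", index=False)
        outputs.append("group_thresholds.tsv")
        return outputs

    def stage_mvpa(self) -> list[str]:
        flags, maps = self._load_contrasts()
        roi_labels = _load_nifti(self.out / "roi_labels.nii").astype(int)
        roi_names = json.loads((self.out / "cohort_manifest.json").read_text())["roi_names"]
        roi_masks = {"whole_brain": roi_labels > 0}
        for lab, name in roi_names.items():
            roi_masks[name] = roi_labels == int(lab)
        mc = self.config.mvpa
        labels = {r["subject_id"]: r["group"] for _, r in flags.iterrows()}
        patterns = {}
        for roi in mc.rois:
            if roi not in roi_masks:
                raise ValueError(f"unknown ROI {roi!r}; available: {sorted(roi_masks)}")
            for fmt, submaps in maps.items():
                patterns[(roi, fmt)] = mvpa.extract_patterns(
                    submaps, roi_masks[roi], roi_name=roi, labels=labels, contrast_label=fmt
                )
        cfg = mvpa.LPOCVConfig(
            n_repetitions=mc.n_repetitions,
            n_permutations=mc.n_permutations,
            classifier=mc.classifier,
            pairing=mc.pairing,
            seed=_stage_rng_seed(self.config.seed, "mvpa"),
        )
        table = mvpa.run_mvpa_suite(patterns, cfg)
        table.to_csv(self.out / "mvpa_results.tsv", sep="\t", index=False)
        outputs = ["mvpa_results.tsv"]
        if mc.save_null_distributions:
            nulls = []
            for (roi, fmt, kind, comp), res in table.attrs.get("results", {}).items():
                for v in res.null_distribution:
                    nulls.append((roi, fmt, kind, comp, float(v)))
            pd.DataFrame(nulls, columns=["roi", "contrast", "analysis", "comparison", "null_accuracy"]).to_csv(
                self.out / "mvpa_null_distributions.tsv.gz", sep="\t", index=False, compression="gzip"
            )
            outputs.append("mvpa_null_distributions.tsv.gz")
        return outputs

    def stage_behavior(self) -> list[str]:
        table = pd.read_csv(self.out / "behavior.tsv", sep="\t")
        _, summary = behavior_mod.filter_trials(table)
        summary.to_csv(self.out / "behavior_cells.tsv", sep="\t", index=False)
        outputs = ["behavior_cells.tsv"]
        frames = []
        for measure in ("accuracy", "rt", "nonresponse"):
            wide = behavior_mod.aggregate_cells(table, measure, rt_trials=self.config.behavior.rt_trials)
            anova = behavior_mod.mixed_anova(wide)
            t = anova.table.copy()
            t.insert(0, "measure", measure)
            frames.append(t)
            pw = behavior_mod.pairwise_format_comparisons(wide)
            pw.insert(0, "measure", measure)
            pw.to_csv(self.out / f"behavior_pairwise_{measure}.tsv", sep="\t", index=False)
            outputs.append(f"behavior_pairwise_{measure}.tsv")
        pd.concat(frames).to_csv(self.out / "behavior_anova.tsv", sep="\t", index=False)
        outputs.append("behavior_anova.tsv")
        return outputs

    # -- orchestration ------------------------------------------------------

    def run(self) -> dict:
        """Run all enabled stages in dependency order; returns the run report."""
        self.config.to_yaml(self.out / "config_resolved.yaml")
        report = {"stages": {}, "config": "config_resolved.yaml"}
        for stage in STAGE_ORDER:
            if not getattr(self.config.stages, stage):
                report["stages"][stage] = {"status": "disabled"}
                continue
            if self._is_done(stage):
                rec = json.loads(self._done_path(stage).read_text())
                report["stages"][stage] = {"status": "cached", **rec}
                continue
            t0 = time.time()
            log.info("running stage %s", stage)
            try:
                outputs = getattr(self, f"stage_{stage}")()
            except Exception as e:
                report["stages"][stage] = {"status": "failed", "error": str(e)}
                (self.out / "run_report.json").write_text(json.dumps(report, indent=1))
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            rec = self._mark_done(stage, outputs)
            report["stages"][stage] = {"status": "ok", "seconds": round(time.time() - t0, 2), **rec}
        (self.out / "run_report.json").write_text(json.dumps(report, indent=1))
        return report


def run_pipeline(config: PipelineConfig) -> dict:
    return PipelineRunner(config).run()


def render_report(out_dir: str | Path) -> str:
    """Render a human-readable markdown summary of a completed run."""
    out = Path(out_dir)
    lines = ["# Pipeline report", ""]
    qc_summary = out / "qc_summary.json"
    if qc_summary.exists():
        s = json.loads(qc_summary.read_text())
        lines += [
            "## Motion QC",
            "",
            f"- runs excluded: {s['n_runs_excluded']} ({s['pct_runs_excluded']:.2f}%)",
            f"- subjects excluded: {s['n_subjects_excluded']} of {s['n_subjects']}",
            "",
        ]
    for name, title in [
        ("behavior_anova.tsv", "Behavioral mixed ANOVAs"),
        ("group_thresholds.tsv", "Voxelwise group thresholds"),
        ("mvpa_results.tsv", "MVPA subject classification and generalization"),
    ]:
        p = out / name
        if not p.exists():
            continue
        df = pd.read_csv(p, sep="\t")
        lines += [f"## {title}", ""]
        if df.empty:
            lines += ["(no rows)", ""]
        else:
            lines += [df.to_markdown(index=False), ""]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
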