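"""Unit and property tests for the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from ldpatterns import cohort, first_level


class TestRunDesign:
    def test_trials_per_format(self, timing, run_design):
        for fmt in timing.formats:
            assert run_design.trial_count(fmt) == 12

    def test_format_block_duration_is_15s(self, timing):
        # 900 + 3 * (300 + 4400) ms
        assert timing.format_block_s == pytest.approx(15.0)
        assert timing.format_block_s == pytest.approx(timing.fixation_block_s)

    def test_blocks_alternate_and_are_balanced(self, timing, run_design):
        conds = list(run_design.blocks["condition"])
        assert conds[0] == "fixation" and conds[-1] == "fixation"
        for a, b in zip(conds, conds[1:]):
            assert (a == "fixation") != (b == "fixation"), "fixation and format blocks must alternate"
        for fmt in timing.formats:
            assert conds.count(fmt) == timing.blocks_per_format

    def test_events_ordered_and_non_overlapping(self, run_design):
        ev = run_design.events.sort_values("onset_s")
        ends = (ev["onset_s"] + ev["duration_s"]).to_numpy()
        starts = ev["onset_s"].to_numpy()
        assert np.all(starts[1:] >= ends[:-1] - 1e-9)

    def test_n_scans_covers_run(self, timing, run_design):
        total = run_design.blocks["duration_s"].sum()
        assert run_design.n_scans == int(np.ceil(total / timing.tr_s)) == 125

    def test_degenerate_single_trial(self):
        t = cohort.TimingParams(items_per_block=1, blocks_per_format=1)
        d = cohort.generate_run_design(t, 0)
        for fmt in t.formats:
            assert d.trial_count(fmt) == 1

    def test_reference_magnitude_cycle(self, timing):
        mags = [cohort.generate_run_design(timing, r).reference_magnitude for r in range(4)]
        assert mags == [4, 5, 4, 5]

    @pytest.mark.parametrize("bad_field", ["reference_ms", "item_ms", "tr_s"])
    def test_invalid_timing_names_field(self, bad_field):
        with pytest.raises(ValueError, match=bad_field):
            cohort.TimingParams(**{bad_field: -1})

    def test_same_seed_same_design(self, timing):
        d1 = cohort.generate_run_design(timing, 2, seed=7)
        d2 = cohort.generate_run_design(timing, 2, seed=7)
        pd.testing.assert_frame_equal(d1.events, d2.events)


class TestMotionTrace:
    def test_zero_severity_is_still(self):
        tr = cohort.generate_motion_trace(50, severity=0.0, seed=3)
        assert np.all(tr.params == 0)

    def test_same_seed_identical(self):
        a = cohort.generate_motion_trace(80, severity=0.1, seed=5)
        b = cohort.generate_motion_trace(80, severity=0.1, seed=5)
        np.testing.assert_array_equal(a.params, b.params)

    def test_spike_injected(self):
        tr = cohort.generate_motion_trace(30, severity=0.0, spike_spec=(10, 0, 2.5, 2), seed=0)
        steps = np.diff(tr.params[:, 0])
        assert steps[10] == pytest.approx(2.5) and steps[11] == pytest.approx(2.5)
        assert np.all(steps[:10] == 0)

    def test_spike_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            cohort.generate_motion_trace(10, spike_spec=(9, 0, 2.5, 2), seed=0)

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValueError, match="n_scans"):
            cohort.generate_motion_trace(1)


class TestAmplitudeMaps:
    def test_rho_one_makes_deviations_identical(self, small_structure):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, rho_shared=1.0, effect_size_delta=2.0)
        _, _, truth = cohort.generate_amplitude_maps(st, (8, 8, 8), seed=1)
        for fmt in cohort.FORMATS:
            np.testing.assert_allclose(truth.dev_dl[fmt], truth.dev_dc[fmt], atol=1e-12)

    def test_rho_zero_makes_deviations_orthogonal(self):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, rho_shared=0.0, effect_size_delta=2.0)
        _, _, truth = cohort.generate_amplitude_maps(st, (10, 10, 10), seed=1)
        mask = truth.roi_labels > 0
        dot = float(truth.dev_dl["dots"][mask] @ truth.dev_dc["dots"][mask])
        assert abs(dot) < 1e-10

    def test_cosine_equals_rho(self):
        rho = 0.37
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, rho_shared=rho, effect_size_delta=3.0)
        _, _, truth = cohort.generate_amplitude_maps(st, (10, 10, 10), seed=4)
        mask = truth.roi_labels > 0
        a, b = truth.dev_dl["dots"][mask], truth.dev_dc["dots"][mask]
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos == pytest.approx(rho, abs=1e-10)

    def test_delta_zero_gives_single_mean_map(self):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, effect_size_delta=0.0)
        _, _, truth = cohort.generate_amplitude_maps(st, (8, 8, 8), seed=2)
        for fmt in cohort.FORMATS:
            for dl, dc in [(True, False), (False, True), (True, True)]:
                np.testing.assert_allclose(truth.group_mean(fmt, dl, dc), truth.mu[fmt])

    def test_comorbid_rules(self):
        for rule, factor in [("additive", 1.0), ("average", 0.5)]:
            st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, comorbid_rule=rule, effect_size_delta=2.0)
            _, _, truth = cohort.generate_amplitude_maps(st, (8, 8, 8), seed=3)
            np.testing.assert_allclose(
                truth.dev_dldc["dots"], factor * (truth.dev_dl["dots"] + truth.dev_dc["dots"]), atol=1e-12
            )

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rho_shared"):
            cohort.GroupStructure(rho_shared=1.5)

    def test_rho_recovered_from_group_means_at_low_noise(self):
        # >= 10,000 in-brain voxels; subject noise near zero
        rho = 0.6
        st = cohort.GroupStructure(
            n_td=3, n_dl=3, n_dc=3, n_dldc=3, rho_shared=rho, effect_size_delta=4.0, sigma_subject=1e-4
        )
        roi = cohort.default_roi_labels((24, 24, 24), margin=1)
        assert int((roi[0] > 0).sum()) >= 10_000
        flags, amaps, truth = cohort.generate_amplitude_maps(st, (24, 24, 24), roi_spec=roi, seed=9)
        mask = truth.roi_labels > 0
        groups = {}
        for g, sel in [("TD", (False, False)), ("DL", (True, False)), ("DC", (False, True))]:
            members = [amaps[sid].grids["dots"][mask] for sid, dl, dc in flags if (dl, dc) == sel]
            groups[g] = np.mean(members, axis=0)
        dev_dl = groups["DL"] - groups["TD"]
        dev_dc = groups["DC"] - groups["TD"]
        r = np.corrcoef(dev_dl, dev_dc)[0, 1]
        assert r == pytest.approx(rho, abs=0.1)


class TestSynthesizeBold:
    def test_zero_amplitude_zero_noise_is_constant_baseline(self, timing, run_design):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, effect_size_delta=0.0, sigma_subject=0.0)
        flags, amaps, truth = cohort.generate_amplitude_maps(st, (6, 6, 6), seed=0, mu_scale=0.0, mu_offset=0.0)
        am = amaps[flags[0][0]]
        mt = cohort.generate_motion_trace(run_design.n_scans, seed=1)
        bold = cohort.synthesize_bold(am, run_design, mt, timing, noise=(0.0, 0.0), baseline=100.0)
        assert np.all(bold == 100.0)

    def test_n_scans_mismatch_rejected(self, timing, run_design):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2)
        flags, amaps, _ = cohort.generate_amplitude_maps(st, (6, 6, 6), seed=0)
        mt = cohort.generate_motion_trace(run_design.n_scans - 5, seed=1)
        with pytest.raises(ValueError, match="scans"):
            cohort.synthesize_bold(amaps[flags[0][0]], run_design, mt, timing)

    def test_ar1_autocorrelation_matches_direct_simulation(self, timing, run_design):
        """Residual noise lag-1 autocorrelation tracks the AR(1) coefficient."""
        ar1 = 0.4
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, effect_size_delta=0.0, sigma_subject=0.0)
        flags, amaps, _ = cohort.generate_amplitude_maps(st, (10, 10, 10), seed=0, mu_scale=0.0, mu_offset=0.0)
        bold = cohort.synthesize_bold(
            amaps[flags[0][0]],
            run_design,
            cohort.generate_motion_trace(run_design.n_scans, severity=0.0, seed=1),
            timing,
            noise=(ar1, 1.0),
            baseline=0.0,
            seed=5,
        )
        x = bold.reshape(-1, run_design.n_scans)
        assert x.size >= 10_000
        emp = np.mean(
            [np.corrcoef(r[:-1], r[1:])[0, 1] for r in x[np.random.default_rng(0).choice(len(x), 300, replace=False)]]
        )
        # independent oracle: direct AR(1) recursion statistics
        rng = np.random.default_rng(42)
        sims = []
        for _ in range(300):
            e = rng.normal(size=run_design.n_scans)
            z = np.empty_like(e)
            z[0] = e[0] / np.sqrt(1 - ar1**2)
            for t in range(1, len(e)):
                z[t] = ar1 * z[t - 1] + e[t]
            sims.append(np.corrcoef(z[:-1], z[1:])[0, 1])
        assert emp == pytest.approx(np.mean(sims), abs=0.05)


class TestBehavior:
    def test_zero_effects_equal_group_means(self):
        st = cohort.GroupStructure(n_td=30, n_dl=30, n_dc=30, n_dldc=30)
        flat = {g: {f: (0.8, 2.0, 0.1) for f in cohort.FORMATS} for g in cohort.GROUP_NAMES}
        table = cohort.generate_behavior(st, flat, seed=0)
        acc = table.groupby(table["dyslexia"].astype(str) + table["dyscalculia"].astype(str))["correct"].mean()
        assert acc.max() - acc.min() < 0.05

    def test_full_nonresponse_cell_has_no_scored_trials(self):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2)
        eff = {g: {f: (0.8, 2.0, 1.0 if (g == "DC" and f == "dots") else 0.0) for f in cohort.FORMATS} for g in cohort.GROUP_NAMES}
        table = cohort.generate_behavior(st, eff, seed=0)
        dc_dots = table[(table["format"] == "dots") & (~table["dyslexia"]) & table["dyscalculia"]]
        assert dc_dots["correct"].isna().all() and dc_dots["rt_s"].isna().all()

    def test_dyscalculia_dot_deficit_at_large_n(self):
        st = cohort.GroupStructure(n_td=250, n_dl=250, n_dc=250, n_dldc=250)
        table = cohort.generate_behavior(st, seed=1)
        dots = table[table["format"] == "dots"]
        acc_dc = dots[dots["dyscalculia"]]["correct"].mean()
        acc_nodc = dots[~dots["dyscalculia"]]["correct"].mean()
        assert acc_dc < acc_nodc

    def test_invalid_probability_rejected(self):
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2)
        eff = {g: {f: (1.2, 2.0, 0.0) for f in cohort.FORMATS} for g in cohort.GROUP_NAMES}
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            cohort.generate_behavior(st, eff)

    def test_missing_iff_nonresponse(self):
        st = cohort.GroupStructure(n_td=3, n_dl=3, n_dc=3, n_dldc=3)
        table = cohort.generate_behavior(st, seed=2)
        assert (table["correct"].isna() == table["rt_s"].isna()).all()
        scored = table.dropna(subset=["rt_s"])
        assert ((scored["rt_s"] > 0) & (scored["rt_s"] <= 4.4)).all()


class TestCohortAssembly:
    def test_default_cohort_counts(self):
        st = cohort.GroupStructure()
        assert st.n_total == 52
        assert (st.n_td, st.n_dl, st.n_dc, st.n_dldc) == (22, 14, 8, 8)

    def test_trial_slot_conservation(self, small_structure, timing):
        table = cohort.generate_behavior(small_structure, seed=0, timing=timing)
        per_subject = table.groupby("subject_id").size()
        expected = timing.n_runs * len(timing.formats) * timing.blocks_per_format * timing.items_per_block
        assert (per_subject == expected).all()

    def test_simulate_cohort_reproducible(self, small_structure):
        c1 = cohort.simulate_cohort(small_structure, grid_shape=(8, 8, 8), seed=21, p_bad_run=0.2)
        c2 = cohort.simulate_cohort(small_structure, grid_shape=(8, 8, 8), seed=21, p_bad_run=0.2)
        pd.testing.assert_frame_equal(c1.behavior, c2.behavior)
        np.testing.assert_array_equal(c1.subjects[0].motion[1].params, c2.subjects[0].motion[1].params)
        np.testing.assert_array_equal(c1.synthesize_run(2, 3), c2.synthesize_run(2, 3))

    def test_groups_match_flags(self, small_structure):
        c = cohort.simulate_cohort(small_structure, grid_shape=(8, 8, 8), seed=1)
        counts = c.flags["group"].value_counts().to_dict()
        assert counts == {"TD": 4, "DL": 3, "DC": 3, "DLDC": 3}
        assert len(c.subjects[0].motion) == c.timing.n_runs

    def test_noiseless_forward_inverse_consistency(self, timing):
        """Synthesis followed by the GLM returns the stored amplitudes."""
        st = cohort.GroupStructure(n_td=2, n_dl=2, n_dc=2, n_dldc=2, sigma_subject=0.3)
        flags, amaps, _ = cohort.generate_amplitude_maps(st, (8, 8, 8), seed=6)
        d = cohort.generate_run_design(timing, 0, seed=6)
        mt = cohort.generate_motion_trace(d.n_scans, severity=0.05, seed=6)
        am = amaps[flags[3][0]]
        bold = cohort.synthesize_bold(am, d, mt, timing, noise=(0.0, 0.0), motion_coupling=0.0)
        fit = first_level.fit_glm(bold, first_level.build_design_matrix(d, mt, timing))
        for fmt in timing.formats:
            np.testing.assert_allclose(first_level.contrast_map(fit, fmt).values, am.grids[fmt], atol=1e-8)
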