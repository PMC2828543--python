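"""First-level GLM: HRF basis, event screening, design, fitting, contrasts."""

import numpy as np
import pandas as pd
import pytest

from satlab import (
    AgentParams,
    CalibrationProfile,
    apply_contrast,
    build_design,
    build_schedule,
    emit_behavior,
    fit_glm,
    hrf_basis,
    screen_events,
    simulate_bold,
)
from satlab.glm import (
    TR_DEFAULT,
    ContrastSpec,
    DesignMatrix,
    FirstLevelModel,
    contrast_weights,
)


@pytest.fixture(scope="module")
def one_block_log():
    calib = CalibrationProfile(300.0, 20.0)
    from satlab import TaskVersion

    version = TaskVersion.from_high_feature("blue")
    schedule = build_schedule(version, 21, calib)
    return emit_behavior(schedule, AgentParams(), calib, seed=8, subject_id="sub-glm")


@pytest.fixture(scope="module")
def run_design(one_block_log):
    events = screen_events(one_block_log)[0]
    return build_design(events, n_scans=220, tr=TR_DEFAULT)


class TestHRF:
    def test_canonical_peak_near_five_seconds(self):
        basis = hrf_basis(0.1)
        assert basis.time[np.argmax(basis.canonical)] == pytest.approx(5.0, abs=0.1)
        assert basis.canonical.max() == pytest.approx(1.0)

    def test_temporal_derivative_integrates_to_zero(self):
        basis = hrf_basis(0.05)
        # derivative of a transient: integral vanishes up to edge effects
        assert abs(np.trapezoid(basis.temporal_derivative, basis.time)) < 0.02 * np.trapezoid(
            basis.canonical, basis.time
        )

    def test_matches_spm_convention_oracle(self):
        """Cross-check the double-gamma shape against nilearn's SPM HRF."""
        from nilearn.glm.first_level.hemodynamic_models import spm_hrf

        dt = 0.1
        ours = hrf_basis(dt).canonical
        ref = spm_hrf(1.0, oversampling=int(1 / dt), time_length=32.0)
        n = min(len(ours), len(ref))
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.999

    def test_bad_resolution(self):
        with pytest.raises(ValueError):
            hrf_basis(0.0)


class TestScreenEvents:
    def test_all_valid_nothing_dropped(self, blue_version):
        calib = CalibrationProfile(300.0, 20.0)
        schedule = build_schedule(blue_version, 3, calib)
        params = AgentParams(omission_rate=0.0, premature_rate=0.0)
        log = emit_behavior(schedule, params, calib, seed=2)
        for ev in screen_events(log):
            assert ev.n_excluded_cues == 0
            assert len(ev.cues) == 64
            assert len(ev.outcomes) == 64

    def test_omissions_and_early_responses_drop_cue_only(self, one_block_log):
        import copy

        from satlab.task import TrialResult

        log = copy.deepcopy(one_block_log)
        # omission on trial 0; response 0.9 s after cue onset on trial 1
        t1 = log.schedule.blocks[0][1]
        rt_early = (0.9 - t1.probe_delay_s) * 1000.0
        log.trial_results[0][0] = TrialResult(None, "omitted", 5, "Missed")
        log.trial_results[0][1] = TrialResult(rt_early, "premature", 5, "TooEarly")
        ev = screen_events(log)[0]
        base = screen_events(one_block_log)[0]
        assert ev.n_excluded_cues >= base.n_excluded_cues + 2
        assert len(ev.outcomes) == 64  # outcomes always modelled

    def test_outcome_magnitudes_are_payouts(self, one_block_log):
        ev = screen_events(one_block_log)[0]
        payouts = [r.payout_pence for r in one_block_log.trial_results[0]]
        assert ev.outcomes["magnitude"].tolist() == payouts


class TestBuildDesign:
    def test_column_count_with_drift(self, one_block_log):
        # 300 scans at TR 2.73 with a 128 s cutoff: 12 drift columns,
        # 6 conditions x 3 bases + 12 + intercept = 31
        events = screen_events(one_block_log)[0]
        design = build_design(events, n_scans=300)
        assert len(design.drift_columns) == 12
        assert len(design.columns) == 18 + 12 + 1

    def test_empty_condition_flagged_and_zero(self, one_block_log):
        import copy

        log = copy.deepcopy(one_block_log)
        events = screen_events(log)[0]
        events.cues = events.cues[events.cues["condition"] != "red_object"]
        design = build_design(events, n_scans=220)
        assert "red_object" in design.empty_conditions
        assert (design.frame["red_object:hrf"] == 0).all()

    def test_onset_shift_by_one_tr_shifts_columns(self, one_block_log):
        events = screen_events(one_block_log)[0]
        d0 = build_design(events, n_scans=250)
        shifted = screen_events(one_block_log)[0]
        shifted.cues = shifted.cues.assign(onset=shifted.cues["onset"] + TR_DEFAULT)
        shifted.outcomes = shifted.outcomes.assign(
            onset=shifted.outcomes["onset"] + TR_DEFAULT
        )
        d1 = build_design(shifted, n_scans=250)
        a = d0.frame["blue_animal:hrf"].to_numpy()
        b = d1.frame["blue_animal:hrf"].to_numpy()
        assert np.allclose(a[:-1], b[1:], atol=1e-10)

    def test_events_beyond_run_end_rejected(self, one_block_log):
        events = screen_events(one_block_log)[0]
        with pytest.raises(ValueError):
            build_design(events, n_scans=50)


class TestFit:
    def test_exact_recovery_zero_noise(self, run_design):
        amplitudes = {"blue_animal:hrf": 1.5, "outcome:hrf": -0.7, "drift_01": 2.0}
        y = simulate_bold(run_design, amplitudes)
        res = fit_glm(y, run_design)
        betas = res.betas(0)[0]
        for name, amp in amplitudes.items():
            assert betas[name] == pytest.approx(amp, abs=1e-8)
        for name in ("red_object:hrf", "outcome_x_magnitude:hrf"):
            assert betas[name] == pytest.approx(0.0, abs=1e-8)

    def test_white_noise_rho_near_zero(self, one_block_log):
        events = screen_events(one_block_log)[0]
        design = build_design(events, n_scans=500)
        rng = np.random.default_rng(4)
        y = simulate_bold(design, {}, noise_sd=1.0, rho=0.0, n_voxels=20, rng=rng)
        res = fit_glm(y, design)
        assert abs(res.rho[0]) < 0.05

    def test_ar1_noise_rho_recovered(self, one_block_log):
        events = screen_events(one_block_log)[0]
        design = build_design(events, n_scans=500)
        rng = np.random.default_rng(5)
        y = simulate_bold(design, {}, noise_sd=1.0, rho=0.3, n_voxels=20, rng=rng)
        res = fit_glm(y, design)
        assert res.rho[0] == pytest.approx(0.3, abs=0.05)

    def test_rank_deficiency_names_columns(self, run_design):
        frame = run_design.frame.copy()
        frame["dup"] = frame["blue_animal:hrf"]
        bad = DesignMatrix(frame=frame, tr=run_design.tr)
        y = np.zeros((bad.n_scans, 1))
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_glm(y, bad)

    def test_scan_mismatch_rejected(self, run_design):
        with pytest.raises(ValueError):
            fit_glm(np.zeros((10, 1)), run_design)


class TestContrasts:
    def relabel(self, high="animal"):
        low = "object" if high == "animal" else "animal"
        return {"subjective_high": high, "subjective_low": low, "tie": False}

    def test_adaptive_contrast_recovers_injection(self, one_block_log, run_design):
        # +1 on each blue cue type, -1 on each red: contrast value 2c
        c = 0.8
        amps = {"blue_animal:hrf": c, "blue_object:hrf": c,
                "red_animal:hrf": -c, "red_object:hrf": -c}
        y = simulate_bold(run_design, amps)
        res = fit_glm(y, run_design, version=one_block_log.version)
        val = res.contrast("adaptive").value
        assert val[0] == pytest.approx(2 * c, rel=1e-6)

    def test_aberrant_symmetric_response_is_null(self, one_block_log, run_design):
        amps = {f"{ct}:hrf": 1.0 for ct in
                ("blue_animal", "blue_object", "red_animal", "red_object")}
        y = simulate_bold(run_design, amps)
        res = fit_glm(y, run_design, version=one_block_log.version)
        val = apply_contrast(res, "aberrant", relabel=[self.relabel()])
        assert val[0] == pytest.approx(0.0, abs=1e-8)

    def test_aberrant_flip_antisymmetry(self, one_block_log, run_design):
        amps = {"blue_animal:hrf": 1.0, "red_animal:hrf": 0.5}
        y = simulate_bold(run_design, amps)
        res = fit_glm(y, run_design, version=one_block_log.version)
        forward = apply_contrast(res, "aberrant", relabel=[self.relabel("animal")])
        flipped = apply_contrast(res, "aberrant", relabel=[self.relabel("object")])
        assert forward[0] == pytest.approx(-flipped[0])

    def test_tie_relabel_warns(self, one_block_log, run_design):
        y = simulate_bold(run_design, {})
        res = fit_glm(y, run_design, version=one_block_log.version)
        tie = dict(self.relabel(), tie=True)
        with pytest.warns(UserWarning, match="tie"):
            res.contrast("aberrant", relabel=[tie])

    def test_drift_absorbs_slow_sine(self, one_block_log, run_design):
        c = 1.2
        amps = {"blue_animal:hrf": c, "blue_object:hrf": c,
                "red_animal:hrf": -c, "red_object:hrf": -c}
        y = simulate_bold(run_design, amps)
        t = np.arange(run_design.n_scans) * run_design.tr
        y_drift = y + 5.0 * np.sin(2 * np.pi * t / 300.0)[:, None]  # period 300 s
        v0 = fit_glm(y, run_design, version=one_block_log.version).contrast("adaptive").value[0]
        v1 = fit_glm(y_drift, run_design, version=one_block_log.version).contrast("adaptive").value[0]
        assert v1 == pytest.approx(v0, rel=0.02)

    def test_multirun_relabel_flip_changes_sign_per_run(self, one_block_log):
        """A level can be subjective-high in one block and low in another."""
        events = screen_events(one_block_log)
        designs = [build_design(ev, n_scans=220) for ev in events[:2]]
        amps = {"blue_animal:hrf": 1.0, "red_animal:hrf": 1.0,
                "blue_object:hrf": -1.0, "red_object:hrf": -1.0}
        data = [simulate_bold(d, amps) for d in designs]
        relabels = [self.relabel("animal"), self.relabel("object")]
        model = FirstLevelModel(designs, data, version=one_block_log.version,
                                relabels=relabels)
        res = model.fit()
        per_run = res.contrast("aberrant").per_run
        assert per_run[0, 0] == pytest.approx(2.0, rel=1e-6)
        assert per_run[1, 0] == pytest.approx(-2.0, rel=1e-6)
        assert res.contrast("aberrant").value[0] == pytest.approx(0.0, abs=1e-8)

    def test_contrast_weight_vectors(self, blue_version):
        cols = [f"{c}:{b}" for c in
                ("blue_animal", "blue_object", "red_animal", "red_object",
                 "outcome", "outcome_x_magnitude")
                for b in ("hrf", "tderiv", "dderiv")] + ["intercept"]
        w = contrast_weights(cols, "adaptive", blue_version)
        assert w["blue_animal:hrf"] == 0.5 and w["red_object:hrf"] == -0.5
        assert w.drop([f"{c}:hrf" for c in
                       ("blue_animal", "blue_object", "red_animal", "red_object")]).eq(0).all()
        wp = contrast_weights(cols, "parametric_outcome")
        assert wp["outcome_x_magnitude:hrf"] == 1.0 and wp.sum() == 1.0

    def test_explicit_weight_spec(self, run_design):
        y = simulate_bold(run_design, {"outcome:hrf": 3.0})
        res = fit_glm(y, run_design)
        spec = ContrastSpec("custom", weights=pd.Series({"outcome:hrf": 1.0}))
        assert res.contrast(spec).value[0] == pytest.approx(3.0, rel=1e-6)


def test_summary_reports_runs(one_block_log, run_design):
    y = simulate_bold(run_design, {}, noise_sd=1.0, rng=np.random.default_rng(0))
    res = fit_glm(y, run_design)
    summ = res.summary()
    assert summ.loc[1, "n_scans"] == 220
    assert "rho" in summ.columns
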