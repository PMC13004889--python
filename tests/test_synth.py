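import numpy as np
import pandas as pd
import pytest

import tendonload as tl
from tendonload.qc import STATUS_EXCLUDED
from tendonload.synth import Bout, bout_from_duration
from conftest import FS

COLS = ["loading_time_h", "high_time_h", "overall_impulse_bwh", "high_impulse_bwh"]


class TestWaveformBookkeeping:
    def test_rectangular_pulse(self):
        spec = tl.PulseTrainSpec(peak_bw=2.0, pulse_s=36.0, period_s=36.0, shape="rect")
        load, book = tl.generate_load_waveform([Bout(spec, 10.0, 1)], 60.0, FS)
        assert book.overall_impulse_bwh == pytest.approx(0.02)
        assert book.loading_time_h == pytest.approx(36.0 / 3600)
        assert book.high_impulse_bwh == 0.0

    def test_zero_duration(self):
        load, book = tl.generate_load_waveform([], 0.0, FS)
        assert load.size == 0
        assert book == tl.DayLoad()

    def test_empty_bout_contributes_nothing(self):
        b = bout_from_duration(tl.synth.WALKING, 5.0, 0.1)
        assert b.n_pulses == 0
        load, book = tl.generate_load_waveform([b], 30.0, FS)
        assert (load == 0).all() and book.loading_time_h == 0.0

    def test_negative_peak_rejected(self):
        with pytest.raises(tl.DomainError):
            tl.PulseTrainSpec(peak_bw=-1.0, pulse_s=0.5, period_s=1.0)

    @pytest.mark.parametrize("peak, thr", [(3.0, 0.3), (3.2, 3.0), (0.6, 0.3), (4.5, 3.0)])
    def test_closed_form_matches_dense_grid(self, peak, thr):
        """Per-pulse closed forms agree with a fine-grid numerical integral."""
        dur = 0.654
        fs_fine = 20000.0
        u = np.arange(int(dur * fs_fine)) / fs_fine / dur
        y = peak * 0.5 * (1 - np.cos(2 * np.pi * u))
        time_num = (y >= thr).sum() / fs_fine
        imp_num = np.where(y >= thr, y, 0.0).sum() / fs_fine
        assert tl.synth.pulse_time_above(peak, dur, thr) == pytest.approx(
            time_num, rel=5e-3, abs=1e-4)
        assert tl.synth.pulse_impulse_above(peak, dur, thr) == pytest.approx(
            imp_num, rel=5e-3, abs=1e-4)

    def test_train_bookkeeping_matches_dense_grid(self):
        spec = tl.PulseTrainSpec(peak_bw=3.1, pulse_s=0.654, period_s=1.091)
        bout = Bout(spec, 2.0, 50)
        fs_fine = 2000.0
        load, book = tl.generate_load_waveform([bout], 80.0, fs_fine)
        assert book.loading_time_h * 3600 == pytest.approx(
            (load >= 0.3).sum() / fs_fine, rel=5e-3)
        assert book.overall_impulse_bwh * 3600 == pytest.approx(
            np.where(load >= 0.3, load, 0).sum() / fs_fine, rel=5e-3)


class TestForceInversion:
    def test_constant_load_recovered_exactly(self, profile):
        load = np.full(400, 2.0)
        fh, fm, ff = tl.waveform_to_forces(load, FS, tl.DEFAULT_GEOMETRY, profile.body_weight)
        rec = tl.InsoleRecording("P01", "S", profile_start(), FS, fh, fm, ff)
        est = tl.estimate_trace(rec, tl.DEFAULT_GEOMETRY, profile)
        np.testing.assert_allclose(est.load, 2.0, rtol=1e-9)

    def test_zero_trace_zero_forces(self, profile):
        fh, fm, ff = tl.waveform_to_forces(np.zeros(100), FS, body_weight=profile.body_weight)
        assert (fh == 0).all() and (fm == 0).all() and (ff == 0).all()

    def test_gait_roundtrip_within_tolerance(self, profile):
        bout = bout_from_duration(tl.synth.WALKING, 5.0, 120.0)
        load, _ = tl.generate_load_waveform([bout], 140.0, FS)
        fh, fm, ff = tl.waveform_to_forces(load, FS, tl.DEFAULT_GEOMETRY, profile.body_weight)
        rec = tl.InsoleRecording("P01", "S", profile_start(), FS, fh, fm, ff)
        est = tl.estimate_trace(rec, tl.DEFAULT_GEOMETRY, profile)
        nz = load > 0
        assert np.max(np.abs(est.load[nz] - load[nz]) / load[nz]) < 0.02


def profile_start():
    from datetime import datetime

    return datetime(2025, 3, 1, 9)


class TestArtifacts:
    def test_zero_spec_is_identity(self, profile):
        rec = _gait_rec(profile)
        out, log = tl.inject_artifacts(rec, tl.ArtifactSpec.none(), 3)
        np.testing.assert_array_equal(out.f_heel, rec.f_heel)
        np.testing.assert_array_equal(out.f_fore, rec.f_fore)
        assert not log.init_failure

    def test_constant_offset_corrected_by_qc(self, profile):
        rec = _gait_rec(profile)
        spec = tl.ArtifactSpec(noise_sd_n=0.0, offset_prob=1.0, offset_range_n=(50.0, 50.0),
                               drift_prob=0.0, init_failure_prob=0.0)
        corrupted, log = tl.inject_artifacts(rec, spec, 5)
        assert log.offset is not None and log.offset[1] == pytest.approx(50.0)
        corrected, _ = tl.correct_baseline_drift(corrupted)
        mask = tl.detect_unloaded_epochs(rec)
        edges = tl.qc.epoch_edges(rec.n_samples, FS, 10.0)
        for i in np.flatnonzero(mask):
            seg = slice(edges[i], edges[i + 1])
            np.testing.assert_allclose(
                corrected.total_force[seg], rec.total_force[seg], atol=1.0
            )

    def test_init_failure_is_screened_out(self, profile):
        rec = _gait_rec(profile, duration=2400.0)
        spec = tl.ArtifactSpec(init_failure_prob=1.0)
        corrupted, log = tl.inject_artifacts(rec, spec, 11)
        assert log.init_failure
        rules = tl.QCRules(min_duration_s=1800.0)
        _, report = tl.qc_recording(corrupted, profile, rules)
        assert report.status == STATUS_EXCLUDED
        assert report.exclusion_reason == "never-unloaded"


def _gait_rec(profile, duration=300.0):
    from conftest import gait_recording

    rec, _, _ = gait_recording(profile, duration_s=duration, rest_s=40.0)
    return rec


class TestCohortGeneration:
    def test_deterministic(self, tiny_scenario):
        a = tl.generate_cohort(tiny_scenario)
        b = tl.generate_cohort(tiny_scenario)
        assert len(a.recordings) == len(b.recordings)
        for ra, rb in zip(a.recordings, b.recordings):
            assert ra.session_id == rb.session_id
            np.testing.assert_array_equal(ra.f_fore, rb.f_fore)
        pd.testing.assert_frame_equal(
            a.ground_truth.per_participant, b.ground_truth.per_participant
        )
        pd.testing.assert_frame_equal(a.ground_truth.outcomes, b.ground_truth.outcomes)

    def test_ground_truth_additive_over_days(self, tiny_cohort):
        gt = tiny_cohort.ground_truth
        for pid, per_day in gt.day_loads.items():
            total = tl.DayLoad()
            for dl in per_day.values():
                total = total + dl
            row = gt.per_participant.loc[pid]
            assert row["loading_time_h"] == pytest.approx(total.loading_time_h, rel=1e-12)
            assert row["high_impulse_bwh"] == pytest.approx(total.high_impulse_bwh, rel=1e-12, abs=1e-15)

    def test_walking_only_recovery(self):
        cfg = tl.ScenarioConfig(
            n_participants=2, days_min=1, days_max=1, sessions_per_day=(1, 1),
            session_hours=(0.2, 0.3), light_fraction=0.0, exercise_day_prob=0.0,
            artifacts=tl.ArtifactSpec.none(), seed=21,
        )
        cohort = tl.generate_cohort(cfg)
        gt = cohort.ground_truth.per_participant
        res = tl.analyze_cohort(cohort.recordings, cohort.profiles)
        for col in COLS:
            est = res.summaries[col]
            ref = gt[col]
            ok = ref.abs() > 1e-12
            assert (np.abs(est[ok] - ref[ok]) / ref[ok] < 0.02).all()

    def test_infeasible_target_rejected(self):
        with pytest.raises(tl.ConfigError, match="correlation"):
            tl.ScenarioConfig(outcome_targets=(("pas", 1.5),))


class TestOutcomeConstruction:
    def test_comonotone_target_gives_r_one(self):
        rng = np.random.default_rng(0)
        nh = pd.Series(rng.uniform(0.0, 0.3, 60), index=[f"p{i}" for i in range(60)])
        out = tl.draw_outcomes(nh, {"work_150": 1.0}, rng)
        r = np.corrcoef(nh, out["work_150"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_target_recovered_at_n200(self):
        rng = np.random.default_rng(17)
        nh = pd.Series(rng.lognormal(-2.0, 0.6, 200), index=[f"p{i}" for i in range(200)])
        out = tl.draw_outcomes(nh, {"pas": 0.6}, rng)
        r = np.corrcoef(nh, out["pas"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.1)

    def test_strength_class_recovery_across_seeds(self):
        """Empirical r lands in the target's strength class for most seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            nh = pd.Series(rng.lognormal(-2.0, 0.6, 200))
            out = tl.draw_outcomes(nh, {"cmj_height": 0.75}, rng)
            r = np.corrcoef(nh, out["cmj_height"])[0, 1]
            if tl.classify_strength(r) == "strong":
                hits += 1
        assert hits >= 19

    def test_degenerate_reference_warns(self):
        rng = np.random.default_rng(1)
        nh = pd.Series(np.zeros(10))
        with pytest.warns(UserWarning, match="zero variance"):
            out = tl.draw_outcomes(nh, {"pas": 0.6}, rng)
        assert out["pas"].between(1, 6).all()
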