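"""Generator properties: determinism, clamping, monotonicity, ground truth."""

import dataclasses

import numpy as np
import pytest

from neolus.gas import aado2
from neolus.quant import pixel_cov
from neolus.synthetic import (
    BreathingConfig,
    ClipGeometry,
    CohortConfig,
    default_schedule,
    epa_to_grade,
    simulate_blood_gases,
    simulate_breathing_trace,
    simulate_trajectories,
    synthesize_lus_clip,
)
from neolus.breath import breath_length_cov, respiratory_rate, segment_breaths


class TestCohortConfig:
    def test_defaults_encode_study_conditions(self):
        cfg = CohortConfig()
        assert cfg.n_control == 10 and cfg.n_elevated == 9
        sched = np.asarray(cfg.schedule)
        assert sched[0] < 0  # pre-breathing scan
        assert np.all(np.diff(sched) > 0)
        # 2.5-min spacing over the first 10 min, 5-min until 30 min
        assert list(sched[1:5]) == [2.5, 5.0, 7.5, 10.0]
        assert list(sched[5:9]) == [15.0, 20.0, 25.0, 30.0]
        assert sched[-1] == 240.0

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_control": 0},
            {"epa_max": 1.2},
            {"tau_control": 0.0},
            {"schedule": (2.5, 5.0)},  # no pre-breathing time
            {"schedule": (-1.0, 5.0, 5.0)},  # not strictly increasing
            {"backslide_depth": (0.5, 0.2)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CohortConfig(**kw)


class TestTrajectories:
    def test_deterministic_given_seed(self):
        a = simulate_trajectories(CohortConfig(seed=42))
        b = simulate_trajectories(CohortConfig(seed=42))
        for ta, tb in zip(a, b):
            for s in ta.epa:
                np.testing.assert_array_equal(ta.epa[s], tb.epa[s])
            assert ta.backslide_times_min == tb.backslide_times_min

    def test_instant_aeration_limit(self):
        cfg = CohortConfig(
            tau_control=1e-9, tau_elevated=1e-9, epa_noise_sd=0,
            lamb_effect_sd=0, backslide_rate=0, epa_max=0.9,
        )
        for truth in simulate_trajectories(cfg):
            post = truth.timepoints_min > 0
            for s in truth.epa:
                np.testing.assert_allclose(truth.epa[s][post], 0.9)
                np.testing.assert_allclose(truth.epa[s][~post], 0.0)

    def test_noise_free_monotone(self):
        cfg = CohortConfig(epa_noise_sd=0, lamb_effect_sd=0, backslide_rate=0)
        for truth in simulate_trajectories(cfg):
            for s in truth.epa:
                assert np.all(np.diff(truth.epa[s]) >= 0)

    def test_epa_clamped_and_grades_consistent(self):
        for truth in simulate_trajectories(CohortConfig(seed=3, epa_noise_sd=0.3)):
            for s in truth.epa:
                assert np.all((truth.epa[s] >= 0) & (truth.epa[s] <= 1))
                expected = [epa_to_grade(v) for v in truth.epa[s]]
                np.testing.assert_array_equal(truth.grades[s], expected)

    def test_group_separation_across_seeds(self):
        # elevated-liquid lambs aerate more slowly: with tau_elevated twice
        # tau_control the control group mean exceeds the elevated mean at
        # every post-onset time below 3 * tau_elevated in >= 95/100 seeds
        # (trajectory noise at defaults; discrete backsliding events are a
        # separate mechanism and are switched off here)
        wins = 0
        for seed in range(100):
            cfg = CohortConfig(seed=seed, backslide_rate=0.0)
            truths = simulate_trajectories(cfg)
            t = np.asarray(cfg.schedule)
            sel = (t > 0) & (t < 3 * cfg.tau_elevated)
            ctrl = np.mean([tr.mean_epa()[sel] for tr in truths if tr.group == "control"], axis=0)
            elev = np.mean([tr.mean_epa()[sel] for tr in truths if tr.group == "elevated"], axis=0)
            wins += bool(np.all(ctrl > elev))
        assert wins >= 95

    def test_backslide_bookkeeping(self):
        cfg = CohortConfig(seed=11, backslide_rate=3.0, epa_noise_sd=0, lamb_effect_sd=0)
        truths = simulate_trajectories(cfg)
        assert any(truth.backslide_times_min for truth in truths)
        for truth in truths:
            for tm in truth.backslide_times_min:
                assert tm in truth.timepoints_min and tm > 0


class TestClipSynthesis:
    def test_monotone_cov_in_true_epa(self, geometry):
        covs = []
        for e in [0.0, 0.25, 0.5, 0.75, 1.0]:
            clip, info = synthesize_lus_clip(e, geometry, seed=1)
            covs.append(pixel_cov(clip, info["rois"]))
        assert np.all(np.diff(covs) > 0)  # rank correlation 1 on the grid

    def test_pixels_are_8bit_and_deterministic(self, geometry):
        a, _ = synthesize_lus_clip(0.6, geometry, seed=9)
        b, _ = synthesize_lus_clip(0.6, geometry, seed=9)
        assert a.frames.dtype == np.uint8
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_motion_frame_bookkeeping(self, geometry):
        clip, info = synthesize_lus_clip(0.5, geometry, seed=2, n_motion_frames=2)
        assert len(info["motion_frames"]) == 2
        assert clip.n_frames == geometry.n_frames

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            ClipGeometry(height=30)
        with pytest.raises(ValueError):
            synthesize_lus_clip(1.5)

    def test_rois_avoid_rib_shadows(self, geometry):
        _, info = synthesize_lus_clip(0.5, geometry, seed=0)
        shadow = info["shadow_mask"]
        for roi in info["rois"]:
            assert not shadow[roi.x : roi.x + roi.width].any()


class TestBloodGases:
    def test_round_trip_recovers_true_gradient(self):
        cfg = CohortConfig(seed=5)
        truth = simulate_trajectories(cfg)[0]
        records, true_aa = simulate_blood_gases(truth, cfg)
        got = np.array([aado2(r) for r in records])
        np.testing.assert_allclose(got, true_aa, atol=1e-9)

    def test_full_aeration_gives_intercept(self):
        cfg = CohortConfig(
            tau_control=1e-9, tau_elevated=1e-9, epa_max=1.0, epa_noise_sd=0,
            lamb_effect_sd=0, backslide_rate=0, aado2_noise_sd=0, paco2_sd=0,
        )
        truth = simulate_trajectories(cfg)[0]
        _, true_aa = simulate_blood_gases(truth, cfg)
        np.testing.assert_allclose(true_aa, cfg.aado2_intercept, atol=1e-9)

    def test_slope_arithmetic(self):
        # slope 100, intercept 20, EPA 0.6 -> AaDO2 = 60
        cfg = CohortConfig(
            aado2_intercept=20.0, aado2_slope=100.0, aado2_noise_sd=0,
            epa_max=0.6, tau_control=1e-9, tau_elevated=1e-9,
            epa_noise_sd=0, lamb_effect_sd=0, backslide_rate=0,
        )
        truth = simulate_trajectories(cfg)[0]
        _, true_aa = simulate_blood_gases(truth, cfg)
        np.testing.assert_allclose(true_aa, 60.0, atol=1e-9)


class TestBreathingTrace:
    def test_jitter_free_rate_and_regularity(self):
        cfg = BreathingConfig(duration_s=120, breath_jitter_cov=0, channel_noise_sd=0)
        trace, _ = simulate_breathing_trace(cfg)
        breaths = segment_breaths(trace)
        assert respiratory_rate(breaths) == pytest.approx(60.0, abs=1.0)
        assert breath_length_cov(breaths) == pytest.approx(0.0, abs=0.02)

    def test_apnoea_leaves_a_gap(self):
        cfg = BreathingConfig(
            duration_s=180, breath_jitter_cov=0, channel_noise_sd=0, apnoea_s=20.0
        )
        trace, info = simulate_breathing_trace(cfg, events_s=(90.0,))
        breaths = segment_breaths(trace)
        peaks = np.array([b.peak_inspiration for b in breaths]) / trace.sample_rate
        assert np.max(np.diff(peaks)) >= 20.0
        assert max(b.length_s for b in breaths) < 10.0  # no breath spans the gap
        assert info["apnoeas_s"][0][1] - info["apnoeas_s"][0][0] == pytest.approx(20.0)

    def test_overlapping_events_rejected(self):
        cfg = BreathingConfig(duration_s=300)
        with pytest.raises(ValueError, match="overlap"):
            simulate_breathing_trace(cfg, events_s=(90.0, 95.0))

    def test_determinism(self):
        cfg = BreathingConfig(duration_s=60, seed=4, breath_jitter_cov=0.1, channel_noise_sd=0.1)
        a, _ = simulate_breathing_trace(cfg)
        b, _ = simulate_breathing_trace(cfg)
        np.testing.assert_array_equal(a.intrapleural, b.intrapleural)
        np.testing.assert_array_equal(a.tracheal, b.tracheal)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            BreathingConfig(sample_rate=10.0)
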