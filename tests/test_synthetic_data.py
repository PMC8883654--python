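"""Synthetic cohort generator: determinism, anchors, dynamics, recovery."""
import numpy as np
import pytest

from hrvo2.errors import ConfigError, ValidationError
from hrvo2.signal_processing import detect_steady_state, submax_point
from hrvo2.synthetic_data import (
    CohortConfig,
    sample_cohort,
    simulate_recording,
    simulate_study,
    true_vo2,
)


class TestSampleCohort:
    def test_zero_sds_reproduce_configured_means(self):
        cfg = CohortConfig(n_women=2, n_men=2, seed=5).noise_free()
        for p in sample_cohort(cfg):
            assert p.hr_rest == pytest.approx(50.6)
            assert p.hr_max_treadmill == pytest.approx(184.8)
            assert p.hr_max_cycle == pytest.approx(184.8 - 5.0)
            expected_mass = 60.0 if p.sex == "F" else 80.8
            assert p.mass == pytest.approx(expected_mass)
            expected_vo2max = 50.4 if p.sex == "F" else 59.1
            assert p.vo2max_per_kg == pytest.approx(expected_vo2max)

    def test_same_seed_identical_cohort(self):
        cfg = CohortConfig(seed=21)
        a, b = sample_cohort(cfg), sample_cohort(cfg)
        for pa, pb in zip(a, b):
            assert pa == pb

    def test_large_cohort_mean_near_population_value(self):
        cfg = CohortConfig(n_women=500, n_men=500, seed=3)
        cohort = sample_cohort(cfg)
        mean_rest = np.mean([p.hr_rest for p in cohort])
        assert mean_rest == pytest.approx(50.6, abs=0.5)

    def test_true_lines_hit_both_anchors(self):
        cfg = CohortConfig(n_women=1, n_men=1, seed=9)
        for p in sample_cohort(cfg):
            for modality, hr_max in (("cycle", p.hr_max_cycle),
                                     ("run", p.hr_max_treadmill)):
                a, b = p.lines[modality]
                assert a + b * p.hr_rest == pytest.approx(p.vo2_rest_l_min)
                assert a + b * hr_max == pytest.approx(p.vo2max_l_min)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(hr_noise_sd=-1.0)
        with pytest.raises(ConfigError):
            CohortConfig(n_women=0, n_men=0)


class TestTrueVo2:
    def test_walking_speed_zero_is_resting_cost(self):
        assert true_vo2("walk", 0.0, 70.0) == pytest.approx(70 * 3.5 / 1000)

    def test_monotone_along_protocol_grids(self):
        cfg = CohortConfig()
        for modality, grid in (("cycle", cfg.cycle_watts),
                               ("walk", cfg.walk_speeds_kmh),
                               ("run", cfg.run_speeds_kmh)):
            costs = [true_vo2(modality, w, 70.0, cfg) for w in grid]
            assert all(np.diff(costs) > 0)

    def test_cycling_linear_in_watts(self):
        cfg = CohortConfig()
        delta = true_vo2("cycle", 150, 70.0, cfg) - true_vo2("cycle", 50, 70.0, cfg)
        assert delta == pytest.approx(100 * cfg.k_cycle, abs=1e-12)

    def test_negative_workload_rejected(self):
        with pytest.raises(ValidationError):
            true_vo2("cycle", -50, 70.0)


class TestSimulateRecording:
    def _profile(self, cfg):
        return sample_cohort(cfg)[0]

    def test_no_noise_zero_tau_constant_series(self):
        cfg = CohortConfig(n_women=1, n_men=0, seed=2).noise_free()
        p = self._profile(cfg)
        rng = np.random.default_rng(0)
        rec = simulate_recording(p, "cycle", 100.0, 360, rng, cfg)
        vo2_ss = true_vo2("cycle", 100.0, p.mass, cfg)
        hr_ss = p.hr_at_vo2("cycle", vo2_ss)
        assert np.allclose(rec.hr, hr_ss)
        assert np.allclose(rec.vo2, vo2_ss)

    def test_exponential_approach_reaches_target(self):
        from dataclasses import replace

        cfg = replace(CohortConfig(n_women=1, n_men=0, seed=2).noise_free(),
                      tau_s=40.0)
        p = self._profile(cfg)
        rng = np.random.default_rng(0)
        rec = simulate_recording(p, "cycle", 100.0, 360, rng, cfg)
        vo2_ss = true_vo2("cycle", 100.0, p.mass, cfg)
        hr_ss = p.hr_at_vo2("cycle", vo2_ss)
        assert detect_steady_state(rec, 3.0, 8) is not None
        point = submax_point(rec)
        assert point.hr == pytest.approx(hr_ss, abs=1.0)
        assert point.vo2 == pytest.approx(vo2_ss, abs=0.02)

    def test_same_seed_identical_samples(self):
        cfg = CohortConfig(n_women=1, n_men=0, seed=2)
        p = self._profile(cfg)
        rec1 = simulate_recording(p, "walk", 5.0, 360,
                                  np.random.default_rng(77), cfg)
        rec2 = simulate_recording(p, "walk", 5.0, 360,
                                  np.random.default_rng(77), cfg)
        assert np.array_equal(rec1.hr, rec2.hr)
        assert np.array_equal(rec1.vo2, rec2.vo2)

    def test_too_short_duration_rejected(self):
        cfg = CohortConfig(n_women=1, n_men=0, seed=2)
        p = self._profile(cfg)
        with pytest.raises(ValidationError):
            simulate_recording(p, "cycle", 100.0, 200,
                               np.random.default_rng(0), cfg)


class TestSimulateStudy:
    def test_deterministic_for_fixed_seed(self):
        cfg = CohortConfig(n_women=1, n_men=1, seed=13)
        cohort = sample_cohort(cfg)
        a = simulate_study(cohort, cfg)
        b = simulate_study(cohort, cfg)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.hr, rb.hr)
            assert np.array_equal(ra.vo2, rb.vo2)

    def test_structure_per_participant(self, noisy_small_study):
        _, recordings, _ = noisy_small_study
        per_pid = {}
        for rec in recordings:
            per_pid.setdefault(rec.participant_id, []).append(rec)
        for recs in per_pid.values():
            assert len(recs) == 18  # rest + 5+1 cycle + 5 walk + 5+1 run
            phases = [r.phase for r in recs]
            assert phases.count("rest") == 1
            assert phases.count("maximal") == 2
            assert phases.count("submax") == 15

    def test_defaults_satisfy_pipeline_preconditions(self, noisy_small_study):
        _, recordings, result = noisy_small_study
        # every submaximal recording produced a steady state
        assert result.steady_windows["found"].all()
        # every maximal test satisfies at least two effort criteria
        assert all(m.valid for m in result.maximal.values())

    def test_max_vo2_dominates_submax_noise_free(self, noise_free_study):
        _, _, result = noise_free_study
        for (pid, modality), pts in result.points.items():
            family = "cycle" if modality == "cycle" else "treadmill"
            vo2_max = result.maximal[(pid, family)].vo2_max
            assert all(p.vo2 <= vo2_max + 1e-9 for p in pts)


class TestNoiseFreeRecovery:
    """End-to-end parameter recovery on a noise-free simulated study."""

    def test_model1_lines_equal_true_lines(self, noise_free_study):
        cohort, _, result = noise_free_study
        by_id = {p.participant_id: p for p in cohort}
        for (pid, modality, kind), model in result.models.items():
            if kind != 1:
                continue
            a, b = by_id[pid].lines[modality]
            assert model.intercept_a == pytest.approx(a, abs=1e-9)
            assert model.slope_b == pytest.approx(b, abs=1e-11)
            assert model.r2 == pytest.approx(1.0, abs=1e-9)

    def test_model2_exact_for_cycling_and_running(self, noise_free_study):
        cohort, _, result = noise_free_study
        by_id = {p.participant_id: p for p in cohort}
        for (pid, modality, kind), model in result.models.items():
            if kind != 2 or modality == "walk":
                continue
            a, b = by_id[pid].lines[modality]
            assert model.intercept_a == pytest.approx(a, abs=1e-9)
            assert model.slope_b == pytest.approx(b, abs=1e-11)

    def test_walk_cycle_relative_difference_equals_offset(
            self, noise_free_study, noise_free_config):
        from hrvo2.group_analysis import mode_difference

        _, _, result = noise_free_study
        est = result.estimates
        sub = est[est.model_kind == 1]
        wide = sub.pivot_table(index="participant_id",
                               columns=["modality", "level_pct"],
                               values="vo2_est")
        for level in (25.0, 45.0, 65.0, 85.0):
            res = mode_difference(wide[("walk", level)], wide[("cycle", level)])
            assert res.mean_rel_diff == pytest.approx(
                noise_free_config.walking_offset_pct, abs=1e-9)
            assert res.sd_rel_diff == pytest.approx(0.0, abs=1e-9)
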