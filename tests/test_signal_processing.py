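"""Signal-processing extraction rules: resting HR, steady states, maxima."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrvo2.errors import InsufficientDataError, NoSteadyStateError
from hrvo2.signal_processing import (
    detect_steady_state,
    max_test_valid,
    max_values,
    maximal_result,
    resting_hr,
    submax_point,
)
from hrvo2.types import Recording, Workload


def _recording(hr, vo2, **kwargs):
    hr = np.asarray(hr, float)
    defaults = dict(participant_id="P01", occasion=2, modality="cycle",
                    workload=Workload(label="100W", watts=100.0))
    defaults.update(kwargs)
    return Recording(t_start=np.arange(hr.size) * 15.0, hr=hr,
                     vo2=np.asarray(vo2, float), **defaults)


def brute_force_steady(hr, threshold, duration):
    """Independent exhaustive scan over all windows (oracle)."""
    best = None
    for start in range(len(hr) - duration + 1):
        window = hr[start:start + duration]
        if max(window) - min(window) <= threshold:
            best = (start, start + duration)
    return best


class TestRestingHr:
    def test_constant_series(self):
        assert resting_hr(np.full(120, 50.0), window_minutes=5) == 50.0

    def test_piecewise_constant_uses_last_window(self):
        hr = np.concatenate([np.full(20, 60.0), np.full(20, 52.0)])
        assert resting_hr(hr, window_minutes=5) == 52.0

    def test_noisy_series_matches_direct_mean(self, rng):
        hr = 55 + rng.normal(0, 3, size=120)
        expected = sum(hr[-20:]) / 20  # brute-force mean of last 20 samples
        assert resting_hr(hr, window_minutes=5) == pytest.approx(expected, abs=1e-12)

    def test_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            resting_hr(np.full(10, 50.0), window_minutes=5)


class TestDetectSteadyState:
    def test_pure_ramp_has_no_plateau(self):
        hr = 100 + np.arange(40.0)
        assert detect_steady_state(hr, 3.0, 8) is None

    def test_flat_tail_found_at_end(self):
        hr = np.concatenate([100 + np.arange(20.0), np.full(12, 140.0)])
        assert detect_steady_state(hr, 3.0, 8) == (24, 32)

    @given(st.integers(0, 2 ** 32 - 1), st.integers(12, 60),
           st.sampled_from([2.0, 3.0]))
    def test_equals_exhaustive_scan(self, seed, n, threshold):
        rng = np.random.default_rng(seed)
        hr = 120 + np.cumsum(rng.normal(0, 1.2, size=n))
        hr = np.maximum(hr, 1.0)
        assert detect_steady_state(hr, threshold, 8) == \
            brute_force_steady(list(hr), threshold, 8)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_steady_state(np.full(5, 100.0), 3.0, 8)


class TestSubmaxPoint:
    def test_flat_tail_values(self):
        hr = np.concatenate([100 + np.arange(20.0), np.full(12, 140.0)])
        vo2 = np.concatenate([np.linspace(1, 1.9, 20), np.full(12, 2.0)])
        point = submax_point(_recording(hr, vo2))
        assert point.hr == pytest.approx(140.0)
        assert point.vo2 == pytest.approx(2.0)
        assert point.source == "submax_steady"

    def test_uses_last_minute_of_window_only(self):
        # steady window: first minute at 139, last minute at 141 (range 2 <= 3)
        hr = np.concatenate([100 + 2 * np.arange(18.0), np.full(4, 139.0),
                             np.full(4, 141.0)])
        vo2 = np.concatenate([np.linspace(1, 1.8, 18), np.full(4, 1.9),
                              np.full(4, 2.1)])
        point = submax_point(_recording(hr, vo2))
        assert point.hr == pytest.approx(141.0)
        assert point.vo2 == pytest.approx(2.1)

    def test_matches_index_arithmetic_oracle(self, rng):
        hr = np.concatenate([110 + 3 * np.arange(16.0),
                             140 + rng.normal(0, 0.4, size=10)])
        vo2 = np.concatenate([np.linspace(1, 2, 16),
                              2.1 + rng.normal(0, 0.01, size=10)])
        rec = _recording(hr, vo2)
        start, stop = detect_steady_state(rec, 3.0, 8)
        # samples 5-8 of the detected window, averaged independently
        expected_hr = hr[start + 4:start + 8].mean()
        expected_vo2 = vo2[start + 4:start + 8].mean()
        point = submax_point(rec)
        assert point.hr == pytest.approx(expected_hr, abs=1e-12)
        assert point.vo2 == pytest.approx(expected_vo2, abs=1e-12)

    def test_no_steady_state_names_the_recording(self):
        hr = 100 + np.arange(40.0)
        rec = _recording(hr, np.linspace(1, 2, 40))
        with pytest.raises(NoSteadyStateError, match="P01.*cycle.*100W"):
            submax_point(rec)


class TestMaxValues:
    def test_monotone_series_uses_last_window(self):
        hr = 100 + np.arange(20.0)
        vo2 = np.linspace(1, 3, 20)
        hr_max, vo2_max = max_values(_recording(hr, vo2))
        assert hr_max == pytest.approx(hr[-4:].mean())
        assert vo2_max == pytest.approx(vo2[-4:].mean())

    def test_exactly_four_samples(self):
        hr_max, vo2_max = max_values(_recording([150, 160, 170, 180],
                                                [3.0, 3.1, 3.2, 3.3]))
        assert hr_max == pytest.approx(165.0)
        assert vo2_max == pytest.approx(3.15)

    def test_matches_exhaustive_enumeration(self, rng):
        hr = 100 + 2 * np.arange(30.0) + rng.normal(0, 2, 30)
        vo2 = np.linspace(1, 3.4, 30) + rng.normal(0, 0.05, 30)
        best = max(
            (vo2[s:s + 4].mean(), s) for s in range(27)
        )
        hr_max, vo2_max = max_values(_recording(np.maximum(hr, 1), vo2))
        s = best[1]
        assert vo2_max == pytest.approx(vo2[s:s + 4].mean(), abs=1e-12)
        assert hr_max == pytest.approx(hr[s:s + 4].mean(), abs=1e-12)

    def test_ties_resolve_to_later_window(self):
        vo2 = np.array([2.0, 2.0, 2.0, 2.0, 1.0, 2.0, 2.0, 2.0, 2.0])
        hr = np.array([150.0] * 4 + [140.0] + [160.0] * 4)
        hr_max, _ = max_values(_recording(hr, vo2))
        assert hr_max == pytest.approx(160.0)

    def test_short_series_raises(self):
        with pytest.raises(InsufficientDataError):
            max_values(_recording([150, 160, 170], [3.0, 3.1, 3.2]))


class TestMaxTestValid:
    @pytest.mark.parametrize("plateau,rer,rpe,expected_met,expected_valid", [
        (140.0, 1.05, 18, {"plateau", "rpe"}, True),
        (200.0, 1.00, 12, set(), False),
        (None, 1.10, 17, {"rer", "rpe"}, True),   # boundaries inclusive
        (149.9, None, None, {"plateau"}, False),
        (None, 1.0999, 16.9, set(), False),
    ])
    def test_criteria(self, plateau, rer, rpe, expected_met, expected_valid):
        met, valid = max_test_valid(plateau, rer, rpe)
        assert met == frozenset(expected_met)
        assert valid is expected_valid

    def test_maximal_result_computes_plateau_from_series(self):
        # final minute only 50 mL/min above the previous one -> plateau
        hr = np.concatenate([np.linspace(120, 180, 8), np.full(4, 185.0)])
        vo2 = np.concatenate([np.linspace(2.0, 3.0, 4), np.full(4, 3.30),
                              np.full(4, 3.35)])
        rec = _recording(hr, vo2, phase="maximal", rpe_legs=19, rer=1.12)
        res = maximal_result(rec)
        assert res.criteria_met == frozenset({"plateau", "rer", "rpe"})
        assert res.valid
        assert res.plateau_increment == pytest.approx(50.0)
        assert res.vo2_max == pytest.approx(3.35)


class TestPrependInvariance:
    """End-anchored statistics ignore samples prepended before their windows."""

    def test_resting_submax_max_invariant_to_prefix(self, rng):
        hr_tail = np.concatenate([np.linspace(110, 150, 16),
                                  np.full(12, 150.0)])
        vo2_tail = np.concatenate([np.linspace(1.2, 2.4, 16), np.full(12, 2.5)])
        prefix_hr = 80 + np.arange(10.0)
        prefix_vo2 = np.linspace(0.8, 1.1, 10)
        rec = _recording(hr_tail, vo2_tail)
        rec_pre = _recording(np.concatenate([prefix_hr, hr_tail]),
                             np.concatenate([prefix_vo2, vo2_tail]))
        assert resting_hr(rec.hr, 2) == resting_hr(rec_pre.hr, 2)
        p1, p2 = submax_point(rec), submax_point(rec_pre)
        assert (p1.hr, p1.vo2) == (p2.hr, p2.vo2)
        assert max_values(rec) == max_values(rec_pre)
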