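"""Turn raw 15-s HR/VO2 series into calibration inputs.

Three extraction rules mirror standard indirect-calorimetry practice:

* **Resting HR** is the mean of the final minutes (default 5) of a supine
  resting recording.
* **Submaximal calibration points** require a steady state — a window of
  two consecutive minutes (8 samples) in which HR varies by no more than a
  small band (default 3 beats/min, max minus min).  The paired HR and VO2
  values are then averaged over the *last minute* of that window.
* **Maximal values** are the means of the one-minute window (4 samples)
  with the highest continuous paired values; by default the window
  maximises mean VO2 (mean-HR maximisation is available via ``maximize``).
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InsufficientDataError, NoSteadyStateError, ValidationError
from .types import (
    SAMPLE_INTERVAL_S,
    SOURCE_SUBMAX,
    CalibrationPoint,
    MaximalResult,
    Recording,
)

#: two consecutive minutes of 15-s samples
STEADY_WINDOW_SAMPLES = 8
#: one minute of 15-s samples
MINUTE_SAMPLES = 4

PLATEAU_INCREMENT_ML_MIN = 150.0
RER_CRITERION = 1.10
RPE_CRITERION = 17.0


def _as_array(series, attr: str) -> np.ndarray:
    """Coerce a Recording, Sample sequence or float sequence to an array."""
    if isinstance(series, Recording):
        return getattr(series, attr)
    seq = list(series)
    if seq and hasattr(seq[0], attr):
        return np.array([getattr(s, attr) for s in seq], dtype=float)
    return np.asarray(seq, dtype=float)


def resting_hr(series, window_minutes: float = 5.0,
               sample_interval_s: float = SAMPLE_INTERVAL_S) -> float:
    """Mean HR over the final ``window_minutes`` of a resting series."""
    if window_minutes <= 0:
        raise ValidationError("window_minutes must be positive")
    hr = _as_array(series, "hr")
    n = int(round(window_minutes * 60.0 / sample_interval_s))
    if n < 1:
        raise ValidationError("window shorter than one sample")
    if hr.size < n:
        raise InsufficientDataError(
            f"resting series has {hr.size} samples; need {n} "
            f"for a {window_minutes:g}-min window"
        )
    return float(np.mean(hr[-n:]))


def detect_steady_state(series, hr_range_threshold: float = 3.0,
                        duration_samples: int = STEADY_WINDOW_SAMPLES,
                        ) -> tuple[int, int] | None:
    """Find the last steady-state window of a submaximal series.

    Returns the half-open index range ``(start, stop)`` of the *last*
    window of ``duration_samples`` consecutive samples whose HR range
    (max - min) is within ``hr_range_threshold``, or None when no window
    qualifies.  Absence is a valid return, not an error.
    """
    if hr_range_threshold <= 0:
        raise ValidationError("hr_range_threshold must be positive")
    if duration_samples < 2:
        raise ValidationError("duration_samples must be at least 2")
    hr = _as_array(series, "hr")
    if hr.size < duration_samples:
        raise InsufficientDataError(
            f"series has {hr.size} samples; need {duration_samples}"
        )
    windows = sliding_window_view(hr, duration_samples)
    spans = windows.max(axis=1) - windows.min(axis=1)
    hits = np.flatnonzero(spans <= hr_range_threshold)
    if hits.size == 0:
        return None
    start = int(hits[-1])
    return start, start + duration_samples


def submax_point(recording: Recording, hr_range_threshold: float = 3.0,
                 duration_samples: int = STEADY_WINDOW_SAMPLES,
                 point_samples: int = MINUTE_SAMPLES) -> CalibrationPoint:
    """Extract the steady-state calibration point of a submaximal recording.

    HR and VO2 are averaged over the final ``point_samples`` (the last
    minute) of the detected steady-state window.
    """
    window = detect_steady_state(recording, hr_range_threshold, duration_samples)
    if window is None:
        raise NoSteadyStateError(
            "no steady state: participant "
            f"{recording.participant_id}, modality {recording.modality}, "
            f"workload {recording.workload.label}"
        )
    start, stop = window
    if point_samples > duration_samples:
        raise ValidationError("point_samples cannot exceed duration_samples")
    sl = slice(stop - point_samples, stop)
    return CalibrationPoint(
        hr=float(np.mean(recording.hr[sl])),
        vo2=float(np.mean(recording.vo2[sl])),
        source=SOURCE_SUBMAX,
    )


def max_values(series, window_samples: int = MINUTE_SAMPLES,
               maximize: str = "vo2") -> tuple[float, float]:
    """Maximal (HR, VO2) as means of the best one-minute window.

    Over all windows of ``window_samples`` consecutive samples, selects the
    window with the highest mean VO2 (or mean HR when ``maximize='hr'``);
    ties go to the later window, as maximal effort occurs at test end.
    """
    if maximize not in ("vo2", "hr"):
        raise ValidationError("maximize must be 'vo2' or 'hr'")
    hr = _as_array(series, "hr")
    vo2 = _as_array(series, "vo2")
    if hr.size < window_samples:
        raise InsufficientDataError(
            f"series has {hr.size} samples; need {window_samples}"
        )
    hr_means = sliding_window_view(hr, window_samples).mean(axis=1)
    vo2_means = sliding_window_view(vo2, window_samples).mean(axis=1)
    key = vo2_means if maximize == "vo2" else hr_means
    # argmax on the reversed array -> later window wins exact ties
    best = key.size - 1 - int(np.argmax(key[::-1]))
    return float(hr_means[best]), float(vo2_means[best])


def max_test_valid(plateau_increment: float | None = None,
                   rer: float | None = None,
                   rpe: float | None = None,
                   plateau_threshold: float = PLATEAU_INCREMENT_ML_MIN,
                   rer_threshold: float = RER_CRITERION,
                   rpe_threshold: float = RPE_CRITERION,
                   ) -> tuple[frozenset[str], bool]:
    """Evaluate maximal-effort criteria; missing values count as not met."""
    if plateau_increment is None and rer is None and rpe is None:
        raise ValidationError("at least one maximal-test criterion value required")
    met = set()
    if plateau_increment is not None and plateau_increment < plateau_threshold:
        met.add("plateau")
    if rer is not None and rer >= rer_threshold:
        met.add("rer")
    if rpe is not None and rpe >= rpe_threshold:
        met.add("rpe")
    criteria = frozenset(met)
    return criteria, len(criteria) >= 2


def plateau_increment_ml_min(recording: Recording,
                             window_samples: int = MINUTE_SAMPLES) -> float | None:
    """VO2 increment (mL/min) between the last two minutes of a maximal test.

    Returns None when the recording is too short for two windows.
    """
    vo2 = recording.vo2
    if vo2.size < 2 * window_samples:
        return None
    last = vo2[-window_samples:].mean()
    prev = vo2[-2 * window_samples:-window_samples].mean()
    return float((last - prev) * 1000.0)


def maximal_result(recording: Recording,
                   rer: float | None = None,
                   window_samples: int = MINUTE_SAMPLES,
                   maximize: str = "vo2") -> MaximalResult:
    """Build a full MaximalResult from a maximal recording.

    The plateau increment is computed from the series itself; RER, if
    available, is taken from the recording (or the ``rer`` argument); RPE
    is the larger of the legs/breathing ratings.
    """
    hr_max, vo2_max = max_values(recording, window_samples, maximize)
    increment = plateau_increment_ml_min(recording, window_samples)
    if rer is None:
        rer = recording.rer
    rpes = [r for r in (recording.rpe_legs, recording.rpe_breath) if r is not None]
    rpe = max(rpes) if rpes else None
    criteria, valid = max_test_valid(increment, rer, rpe)
    return MaximalResult(
        hr_max=hr_max,
        vo2_max=vo2_max,
        plateau_increment=increment,
        rer=rer,
        rpe=rpe,
        criteria_met=criteria,
        valid=valid,
    )
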