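"""Core domain containers for the heart-rate method pipeline.

The heart-rate (HR) method estimates oxygen uptake (VO2) from heart rate
through an individually calibrated linear HR-VO2 relationship.  The
containers here carry the data through the stages of that pipeline:

raw 15-s recordings -> steady-state calibration points -> individual
linear calibration models -> VO2 estimates at fixed percentages of
heart-rate reserve (%HRR) -> group-level comparison statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContextError, ValidationError

MODALITIES = ("cycle", "walk", "run")
PHASES = ("rest", "submax", "maximal")

#: provenance labels for calibration points
SOURCE_SUBMAX = "submax_steady"
SOURCE_MAXIMAL = "maximal"

SAMPLE_INTERVAL_S = 15.0


@dataclass(frozen=True)
class Workload:
    """Workload descriptor: watts for cycling, speed (and incline) for treadmill."""

    label: str
    watts: float | None = None
    speed_kmh: float | None = None
    incline_deg: float | None = None


@dataclass(frozen=True)
class Sample:
    """One 15-s mean of paired HR (beats/min) and VO2 (L/min)."""

    t_start: float
    hr: float
    vo2: float

    def __post_init__(self):
        if self.t_start % SAMPLE_INTERVAL_S != 0:
            raise ValidationError(f"t_start {self.t_start} not a multiple of 15 s")
        if not self.hr > 0:
            raise ValidationError(f"hr must be > 0, got {self.hr}")
        if self.vo2 < 0:
            raise ValidationError(f"vo2 must be >= 0, got {self.vo2}")


@dataclass
class Recording:
    """One workload's 15-s HR/VO2 series with metadata.

    Samples are stored as parallel numpy arrays (``t_start``, ``hr``,
    ``vo2``); the ``samples`` property materialises ``Sample`` objects on
    demand.  ``modality`` is None for supine resting recordings.
    """

    participant_id: str
    occasion: int
    modality: str | None
    workload: Workload
    t_start: np.ndarray
    hr: np.ndarray
    vo2: np.ndarray
    phase: str = "submax"
    rpe_legs: int | None = None
    rpe_breath: int | None = None
    rer: float | None = None

    def __post_init__(self):
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if not (self.t_start.shape == self.hr.shape == self.vo2.shape):
            raise ValidationError("t_start, hr, vo2 must have equal length")
        if self.t_start.ndim != 1 or self.t_start.size == 0:
            raise ValidationError("a recording needs at least one sample")
        if np.any(self.t_start % SAMPLE_INTERVAL_S != 0):
            raise ValidationError("sample times must be multiples of 15 s")
        if self.t_start.size > 1 and not np.all(
            np.diff(self.t_start) == SAMPLE_INTERVAL_S
        ):
            raise ValidationError("samples must be strictly increasing at 15-s spacing")
        if np.any(self.hr <= 0):
            raise ValidationError("hr samples must be > 0")
        if np.any(self.vo2 < 0):
            raise ValidationError("vo2 samples must be >= 0")
        if self.modality is not None and self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not 1 <= int(self.occasion) <= 4:
            raise ValidationError("occasion must be in 1..4")
        for rpe in (self.rpe_legs, self.rpe_breath):
            if rpe is not None and not 6 <= rpe <= 20:
                raise ValidationError("RPE must be on the Borg 6-20 scale")

    @classmethod
    def from_samples(cls, participant_id, occasion, modality, workload, samples,
                     **kwargs) -> "Recording":
        samples = list(samples)
        return cls(
            participant_id=participant_id,
            occasion=occasion,
            modality=modality,
            workload=workload,
            t_start=np.array([s.t_start for s in samples], dtype=float),
            hr=np.array([s.hr for s in samples], dtype=float),
            vo2=np.array([s.vo2 for s in samples], dtype=float),
            **kwargs,
        )

    @property
    def samples(self) -> tuple[Sample, ...]:
        return tuple(
            Sample(t, h, v) for t, h, v in zip(self.t_start, self.hr, self.vo2)
        )

    @property
    def n_samples(self) -> int:
        return int(self.t_start.size)

    @property
    def duration_s(self) -> float:
        return float(self.t_start.size * SAMPLE_INTERVAL_S)


@dataclass(frozen=True)
class CalibrationPoint:
    """A paired (HR, VO2) value feeding a calibration fit."""

    hr: float
    vo2: float
    source: str

    def __post_init__(self):
        if not (math.isfinite(self.hr) and math.isfinite(self.vo2)):
            raise ValidationError("calibration point must be finite")
        if not 30.0 <= self.hr <= 230.0:
            raise ValidationError(f"hr {self.hr:.1f} outside plausible range [30, 230]")
        if self.source not in (SOURCE_SUBMAX, SOURCE_MAXIMAL):
            raise ValidationError(f"unknown point source {self.source!r}")


@dataclass(frozen=True)
class MaximalResult:
    """Outcome of a maximal test with effort-validity criteria.

    A maximal test counts as valid when at least two of three criteria are
    met: a VO2 plateau (increment < 150 mL/min), RER >= 1.10, RPE >= 17.
    """

    hr_max: float
    vo2_max: float
    plateau_increment: float | None = None
    rer: float | None = None
    rpe: float | None = None
    criteria_met: frozenset[str] = frozenset()
    valid: bool = False

    def __post_init__(self):
        if self.valid != (len(self.criteria_met) >= 2):
            raise ValidationError("valid flag must equal |criteria_met| >= 2")


@dataclass(frozen=True)
class CalibrationModel:
    """An individual's linear HR -> VO2 map: vo2 = intercept_a + slope_b * hr."""

    participant_id: str
    modality: str
    model_kind: int
    intercept_a: float
    slope_b: float
    r2: float
    n_points: int
    hr_range: tuple[float, float]


@dataclass(frozen=True)
class Prediction:
    """A VO2 prediction with quality flags (flags, never errors)."""

    vo2: float
    extrapolated: bool
    negative: bool


@dataclass(frozen=True)
class HrrContext:
    """Resting and (treadmill) maximal HR anchoring the %HRR scale."""

    hr_rest: float
    hr_max_treadmill: float
    participant_id: str | None = None

    def __post_init__(self):
        if not self.hr_max_treadmill > self.hr_rest:
            raise ContextError(
                f"hr_max_treadmill ({self.hr_max_treadmill}) must exceed "
                f"hr_rest ({self.hr_rest})"
            )

    @property
    def reserve(self) -> float:
        return self.hr_max_treadmill - self.hr_rest


@dataclass(frozen=True)
class IntensityEstimate:
    """Estimated VO2 at one %HRR level for one participant/modality/model."""

    participant_id: str
    modality: str
    model_kind: int
    level_pct: float
    hr_target: float
    vo2_est: float
    extrapolated: bool = False
    negative: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    """Group statistics for one pairwise contrast at one %HRR level.

    Absolute differences are target - reference (L/min); relative
    differences are per-individual percentages of the reference value.
    ``p_raw`` is the two-sided one-sample t-test of the absolute mean
    difference against zero; ``p_adj`` doubles it (Bonferroni for the two
    evaluations of each value), capped at 1.
    """

    contrast: tuple[str, str]
    level_pct: float
    n: int
    mean_abs_diff: float
    sd_abs_diff: float
    ci95_abs: tuple[float, float]
    p_raw: float
    p_adj: float
    significant: bool
    mean_rel_diff: float
    sd_rel_diff: float
    ci95_rel: tuple[float, float]
    p_raw_rel: float
    p_adj_rel: float
    significant_rel: bool
    n_rel: int


@dataclass(frozen=True)
class GroupRegression:
    """An OLS line with 95% coefficient intervals."""

    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    r2: float
    n_points: int
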