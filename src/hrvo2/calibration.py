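"""Individual linear HR -> VO2 calibration models.

Model 1 uses submaximal steady-state points only (five in the reference
protocol); model 2 adds exactly one maximal point, widening the HR range
the line is anchored on.  VO2 is regressed on HR by ordinary least
squares — HR is the field-measured predictor the method inverts.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, ModelCompositionError, ValidationError
from .types import (
    SOURCE_MAXIMAL,
    CalibrationModel,
    CalibrationPoint,
    Prediction,
)


def fit_hr_vo2(points, model_kind: int,
               participant_id: str = "",
               modality: str = "cycle",
               expected_submax: int | None = None) -> CalibrationModel:
    """Fit a calibration line by OLS of VO2 on HR.

    Parameters
    ----------
    points
        Sequence of :class:`CalibrationPoint`.  Model 1 requires all
        points to be submaximal; model 2 requires exactly one
        maximal-source point.
    model_kind
        1 (submaximal only) or 2 (submaximal plus one maximal).
    expected_submax
        Optional check on the number of submaximal points (the reference
        protocol uses five).
    """
    points = list(points)
    if model_kind not in (1, 2):
        raise ValidationError(f"model_kind must be 1 or 2, got {model_kind}")
    if len(points) < 2:
        raise DegenerateFitError("need at least 2 calibration points")
    n_max = sum(1 for p in points if p.source == SOURCE_MAXIMAL)
    if model_kind == 1 and n_max != 0:
        raise ModelCompositionError(
            f"model 1 must use submaximal points only; got {n_max} maximal"
        )
    if model_kind == 2 and n_max != 1:
        raise ModelCompositionError(
            f"model 2 requires exactly one maximal point; got {n_max}"
        )
    if expected_submax is not None and len(points) - n_max != expected_submax:
        raise ModelCompositionError(
            f"expected {expected_submax} submaximal points, "
            f"got {len(points) - n_max}"
        )
    hr = np.array([p.hr for p in points], dtype=float)
    vo2 = np.array([p.vo2 for p in points], dtype=float)
    if np.ptp(hr) == 0:
        raise DegenerateFitError("all HR values identical; cannot fit a line")
    res = stats.linregress(hr, vo2)
    if res.slope <= 0:
        warnings.warn(
            f"non-positive HR-VO2 slope ({res.slope:.4g}) for participant "
            f"{participant_id!r} {modality}: physiologically implausible",
            RuntimeWarning,
            stacklevel=2,
        )
    return CalibrationModel(
        participant_id=participant_id,
        modality=modality,
        model_kind=model_kind,
        intercept_a=float(res.intercept),
        slope_b=float(res.slope),
        r2=float(res.rvalue ** 2),
        n_points=len(points),
        hr_range=(float(hr.min()), float(hr.max())),
    )


def predict_vo2(model: CalibrationModel, hr: float) -> Prediction:
    """Evaluate the calibration line at ``hr``.

    Out-of-range HR and negative VO2 are flagged, never raised: the
    method is routinely applied beyond the calibrated HR span, and such
    estimates remain useful at the group level even when not practically
    applicable individually.
    """
    if not np.isfinite(hr):
        raise ValidationError(f"hr must be finite, got {hr}")
    vo2 = model.intercept_a + model.slope_b * hr
    lo, hi = model.hr_range
    return Prediction(
        vo2=float(vo2),
        extrapolated=bool(hr < lo or hr > hi),
        negative=bool(vo2 < 0),
    )
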