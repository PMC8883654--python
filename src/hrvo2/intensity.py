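"""%HRR intensity anchoring and VO2 estimation at fixed levels.

Percent heart-rate reserve: %HRR = (HR - HRrest) / (HRmax - HRrest) * 100,
with the treadmill maximal HR always anchoring the scale.  The seven ACSM
levels (25-85 %HRR) span very light to vigorous intensity.
"""
from __future__ import annotations

from .calibration import predict_vo2
from .errors import ValidationError
from .types import CalibrationModel, HrrContext, IntensityEstimate

#: ACSM exercise-intensity classification levels (%HRR)
ACSM_LEVELS = (25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0)


def percent_hrr(hr: float, ctx: HrrContext) -> float:
    """Express an exercise HR as a percentage of heart-rate reserve.

    Values outside [0, 100] are returned as-is; callers flag them.
    """
    return (hr - ctx.hr_rest) / ctx.reserve * 100.0


def hr_at_fraction(level_pct: float, ctx: HrrContext) -> float:
    """HR target at a %HRR level; exact inverse of :func:`percent_hrr`."""
    return ctx.hr_rest + level_pct / 100.0 * ctx.reserve


def estimation_grid(model: CalibrationModel, ctx: HrrContext,
                    levels=ACSM_LEVELS) -> list[IntensityEstimate]:
    """Estimate VO2 at each %HRR level for one participant/modality/model."""
    levels = [float(v) for v in levels]
    if sorted(set(levels)) != levels:
        raise ValidationError("levels must be sorted and unique")
    if any(not 0 < v <= 100 for v in levels):
        raise ValidationError("levels must lie in (0, 100]")
    if (ctx.participant_id is not None and model.participant_id
            and model.participant_id != ctx.participant_id):
        raise ValidationError(
            f"model participant {model.participant_id!r} does not match "
            f"context participant {ctx.participant_id!r}"
        )
    out = []
    for level in levels:
        hr_target = hr_at_fraction(level, ctx)
        pred = predict_vo2(model, hr_target)
        out.append(IntensityEstimate(
            participant_id=model.participant_id,
            modality=model.modality,
            model_kind=model.model_kind,
            level_pct=level,
            hr_target=hr_target,
            vo2_est=pred.vo2,
            extrapolated=pred.extrapolated,
            negative=pred.negative,
        ))
    return out
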