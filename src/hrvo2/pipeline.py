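"""Study-level assembly: recordings -> models -> estimates -> report.

Binds the stage modules together with the study's conventions:

* resting HR = last 5 minutes of the occasion-1 supine rest;
* model 2 for cycling uses the maximal cycling point, while walking and
  running both use the maximal treadmill (running) point;
* the %HRR scale is always anchored on the treadmill maximal HR.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import signal_processing as sp
from .calibration import fit_hr_vo2
from .errors import ValidationError
from .intensity import ACSM_LEVELS, estimation_grid
from .types import (
    SOURCE_MAXIMAL,
    CalibrationModel,
    CalibrationPoint,
    HrrContext,
    MaximalResult,
    Recording,
)


@dataclass
class StudyConfig:
    """Processing parameters for a full study run."""

    hr_range_threshold: float = 3.0       # steady-state band, bpm (study: 2-3)
    steady_duration_samples: int = 8      # two minutes
    point_samples: int = 4                # last minute of the steady window
    rest_window_minutes: float = 5.0
    max_window_samples: int = 4
    maximize: str = "vo2"                 # or "hr": which minute counts as maximal
    expected_submax: int | None = 5
    levels: tuple = ACSM_LEVELS
    seed: int = 0


@dataclass
class StudyResult:
    """Everything a processed study produces."""

    rest_hr: dict
    points: dict                          # (pid, modality) -> [CalibrationPoint]
    maximal: dict                         # (pid, family) -> MaximalResult
    models: dict                          # (pid, modality, kind) -> CalibrationModel
    contexts: dict                        # pid -> HrrContext
    estimates: pd.DataFrame
    steady_windows: pd.DataFrame
    report: dict = field(default_factory=dict)


def _max_family(modality: str) -> str:
    return "cycle" if modality == "cycle" else "treadmill"


def extract_features(recordings: list[Recording], config: StudyConfig):
    """Stage 1: resting HRs, steady-state points, maximal results, window log."""
    rest_hr: dict = {}
    points: dict = {}
    maximal: dict = {}
    window_rows = []
    for rec in recordings:
        pid = rec.participant_id
        if rec.phase == "rest":
            if rec.occasion == 1:
                rest_hr[pid] = sp.resting_hr(rec, config.rest_window_minutes)
            continue
        if rec.phase == "maximal":
            res = sp.maximal_result(rec, window_samples=config.max_window_samples,
                                    maximize=config.maximize)
            maximal[(pid, _max_family(rec.modality))] = res
            continue
        window = sp.detect_steady_state(rec, config.hr_range_threshold,
                                        config.steady_duration_samples)
        window_rows.append({
            "participant_id": pid, "modality": rec.modality,
            "workload_label": rec.workload.label,
            "window_start": None if window is None else window[0],
            "window_stop": None if window is None else window[1],
            "found": window is not None,
        })
        point = sp.submax_point(rec, config.hr_range_threshold,
                                config.steady_duration_samples,
                                config.point_samples)
        points.setdefault((pid, rec.modality), []).append(point)
    return rest_hr, points, maximal, pd.DataFrame(window_rows)


def build_models(points: dict, maximal: dict, config: StudyConfig) -> dict:
    """Stage 2: model 1 and (where a maximal test exists) model 2 fits."""
    models = {}
    for (pid, modality), pts in points.items():
        models[(pid, modality, 1)] = fit_hr_vo2(
            pts, 1, participant_id=pid, modality=modality,
            expected_submax=config.expected_submax)
        max_res = maximal.get((pid, _max_family(modality)))
        if max_res is not None:
            max_point = CalibrationPoint(hr=max_res.hr_max, vo2=max_res.vo2_max,
                                         source=SOURCE_MAXIMAL)
            models[(pid, modality, 2)] = fit_hr_vo2(
                pts + [max_point], 2, participant_id=pid, modality=modality,
                expected_submax=config.expected_submax)
    return models


def build_contexts(rest_hr: dict, maximal: dict) -> dict:
    """Stage 3: %HRR contexts (occasion-1 rest, treadmill maximal HR)."""
    contexts = {}
    for pid, hr_rest in rest_hr.items():
        tread = maximal.get((pid, "treadmill"))
        if tread is not None:
            contexts[pid] = HrrContext(hr_rest=hr_rest,
                                       hr_max_treadmill=tread.hr_max,
                                       participant_id=pid)
    return contexts


def build_estimates(models: dict, contexts: dict,
                    config: StudyConfig) -> pd.DataFrame:
    """Stage 4: the estimate grid over participants x modalities x models."""
    rows = []
    for (pid, modality, kind), model in models.items():
        ctx = contexts.get(pid)
        if ctx is None:
            continue
        for est in estimation_grid(model, ctx, config.levels):
            rows.append({
                "participant_id": pid, "modality": modality,
                "model_kind": kind, "level_pct": est.level_pct,
                "hr_target": est.hr_target, "vo2_est": est.vo2_est,
                "extrapolated": est.extrapolated, "negative": est.negative,
            })
    if not rows:
        raise ValidationError("no estimates could be built "
                              "(missing treadmill maximal tests or rest data?)")
    return pd.DataFrame(rows)


def run_study(recordings: list[Recording],
              config: StudyConfig | None = None,
              with_report: bool = True) -> StudyResult:
    """Process a full study's recordings end to end."""
    from .group_analysis import build_report

    config = config or StudyConfig()
    rest_hr, points, maximal, windows = extract_features(recordings, config)
    models = build_models(points, maximal, config)
    contexts = build_contexts(rest_hr, maximal)
    estimates = build_estimates(models, contexts, config)
    report = build_report(estimates) if with_report else {}
    return StudyResult(rest_hr=rest_hr, points=points, maximal=maximal,
                       models=models, contexts=contexts, estimates=estimates,
                       steady_windows=windows, report=report)
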