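"""CSV serialisation, report rendering and pipeline orchestration.

One data dialect: RFC-4180 CSV, UTF-8, '.' decimal.  One row per 15-s
sample; empty cells mark inapplicable fields.  Printed-table rounding
(VO2 two decimals, slopes four, percentages one) is applied only at
render time; raw outputs keep full precision.
"""
from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .pipeline import StudyConfig, StudyResult, run_study
from .types import Recording, Workload

RECORDING_COLUMNS = [
    "participant_id", "occasion", "modality", "phase", "workload_label",
    "watts", "speed_kmh", "incline_deg", "t_start_s", "hr_bpm", "vo2_L_min",
    "rpe_legs", "rpe_breath", "rer",
]

_OPT_FLOAT = ("watts", "speed_kmh", "incline_deg", "rer")
_OPT_INT = ("rpe_legs", "rpe_breath")


def write_recordings(recordings: list[Recording], path) -> None:
    rows = []
    for rec in recordings:
        for t, hr, vo2 in zip(rec.t_start, rec.hr, rec.vo2):
            rows.append({
                "participant_id": rec.participant_id,
                "occasion": rec.occasion,
                "modality": "" if rec.modality is None else rec.modality,
                "phase": rec.phase,
                "workload_label": rec.workload.label,
                "watts": rec.workload.watts,
                "speed_kmh": rec.workload.speed_kmh,
                "incline_deg": rec.workload.incline_deg,
                "t_start_s": t,
                "hr_bpm": hr,
                "vo2_L_min": vo2,
                "rpe_legs": rec.rpe_legs,
                "rpe_breath": rec.rpe_breath,
                "rer": rec.rer,
            })
    # %.17g guarantees float64 values survive the text round trip exactly
    pd.DataFrame(rows, columns=RECORDING_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def _opt(value, cast):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def read_recordings(path) -> list[Recording]:
    """Read and validate a recordings CSV; malformed rows are reported with
    1-based file line numbers."""
    df = pd.read_csv(path, dtype={"participant_id": str, "modality": str,
                                  "phase": str, "workload_label": str},
                     float_precision="round_trip")
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    bad = []
    for col in ("occasion", "t_start_s", "hr_bpm", "vo2_L_min"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad.extend(int(i) + 2 for i in df.index[vals.isna()])
        df[col] = vals
    if bad:
        raise ParseError(f"{path}: malformed numeric values on lines "
                         f"{sorted(set(bad))}")

    keys = ["participant_id", "occasion", "modality", "phase", "workload_label"]
    df["modality"] = df["modality"].fillna("")
    recordings = []
    for key, grp in df.groupby(keys, sort=False):
        pid, occasion, modality, phase, label = key
        grp = grp.sort_values("t_start_s")
        first = grp.iloc[0]
        try:
            recordings.append(Recording(
                participant_id=pid,
                occasion=int(occasion),
                modality=None if modality == "" else modality,
                workload=Workload(
                    label=label,
                    watts=_opt(first["watts"], float),
                    speed_kmh=_opt(first["speed_kmh"], float),
                    incline_deg=_opt(first["incline_deg"], float),
                ),
                t_start=grp["t_start_s"].to_numpy(),
                hr=grp["hr_bpm"].to_numpy(),
                vo2=grp["vo2_L_min"].to_numpy(),
                phase=phase,
                rpe_legs=_opt(first["rpe_legs"], lambda v: int(float(v))),
                rpe_breath=_opt(first["rpe_breath"], lambda v: int(float(v))),
                rer=_opt(first["rer"], float),
            ))
        except Exception as exc:
            lines = [int(i) + 2 for i in grp.index]
            raise ParseError(
                f"{path}: invalid recording {key} "
                f"(lines {lines[0]}-{lines[-1]}): {exc}") from exc
    return recordings


# ---------------------------------------------------------------------------
# report rendering

ROUND_RULES = {
    "vo2": 2, "slope": 4, "pct": 1, "hr": 1, "r2": 3, "intercept": 3,
}

_COLUMN_KIND = {
    "vo2_mean": "vo2", "vo2_sd": "vo2", "vo2_ci_low": "vo2",
    "vo2_ci_high": "vo2", "mean_abs_diff": "vo2", "sd_abs_diff": "vo2",
    "ci_abs_low": "vo2", "ci_abs_high": "vo2",
    "mean_rel_diff": "pct", "sd_rel_diff": "pct",
    "ci_rel_low": "pct", "ci_rel_high": "pct",
    "hr_target_mean": "hr", "hr_target_sd": "hr",
    "slope": "slope", "slope_ci_low": "slope", "slope_ci_high": "slope",
    "intercept": "intercept", "intercept_ci_low": "intercept",
    "intercept_ci_high": "intercept", "r2": "r2",
}


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply printed-precision rounding to a report table (copy)."""
    out = table.copy()
    for col, kind in _COLUMN_KIND.items():
        if col in out.columns:
            out[col] = out[col].round(ROUND_RULES[kind])
    return out


def write_report(result: StudyResult, outdir, rounded: bool = True) -> None:
    """Write estimates, window log and all report tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.estimates.to_csv(outdir / "estimates.csv", index=False)
    result.steady_windows.to_csv(outdir / "steady_windows.csv", index=False)
    models = pd.DataFrame([
        {"participant_id": m.participant_id, "modality": m.modality,
         "model_kind": m.model_kind, "intercept_a": m.intercept_a,
         "slope_b": m.slope_b, "r2": m.r2, "n_points": m.n_points,
         "hr_min": m.hr_range[0], "hr_max": m.hr_range[1]}
        for m in result.models.values()
    ])
    models.to_csv(outdir / "models.csv", index=False)
    contexts = pd.DataFrame([
        {"participant_id": pid, "hr_rest": c.hr_rest,
         "hr_max_treadmill": c.hr_max_treadmill}
        for pid, c in result.contexts.items()
    ])
    contexts.to_csv(outdir / "hrr_contexts.csv", index=False)
    for name, table in result.report.items():
        table.to_csv(outdir / f"{name}.csv", index=False)
        if rounded:
            render_table(table).to_csv(outdir / f"{name}_rounded.csv",
                                       index=False)


# ---------------------------------------------------------------------------
# flat key=value study configuration

def read_study_config(path) -> StudyConfig:
    """Parse a flat ``key = value`` text config into a StudyConfig."""
    cfg = StudyConfig()
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if not hasattr(cfg, key):
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if key == "levels":
            setattr(cfg, key, tuple(float(v) for v in value.split(",")))
        elif isinstance(current, bool):
            setattr(cfg, key, value.lower() in ("1", "true", "yes"))
        elif isinstance(current, int):
            setattr(cfg, key, int(value))
        elif isinstance(current, float):
            setattr(cfg, key, float(value))
        else:
            setattr(cfg, key, value)
    return cfg


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(vars(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_run_log(outdir, config: StudyConfig, result: StudyResult,
                  seed: int | None = None) -> None:
    from . import __version__

    flagged = result.estimates[
        result.estimates["extrapolated"] | result.estimates["negative"]]
    log = {
        "hrvo2_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed if seed is None else seed,
        "config_hash": _config_hash(config),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "n_participants": len(result.contexts),
        "n_estimates": int(len(result.estimates)),
        "n_flagged_estimates": int(len(flagged)),
        "flagged_estimates": flagged[
            ["participant_id", "modality", "model_kind", "level_pct",
             "vo2_est", "extrapolated", "negative"]
        ].to_dict(orient="records"),
    }
    Path(outdir, "run_log.json").write_text(json.dumps(log, indent=2),
                                            encoding="utf-8")


def run_pipeline(recordings_path, outdir,
                 config: StudyConfig | None = None) -> StudyResult:
    """Read recordings, process the study, write the full report bundle."""
    config = config or StudyConfig()
    recordings = read_recordings(recordings_path)
    result = run_study(recordings, config)
    write_report(result, outdir)
    write_run_log(outdir, config, result)
    return result
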