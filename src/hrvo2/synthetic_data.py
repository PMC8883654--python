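"""Synthetic cohorts and raw 15-s recordings for the calibration study design.

No individual-level data from the reference study are available, so this
module generates cohorts with the same statistical structure: 24 active
adults (12 women, 12 men), each performing a supine rest, five submaximal
cycling workloads (50-150 W) plus a maximal cycle ramp, five level walking
speeds (3-7 km/h), and five level running speeds (6-12 km/h) plus a
maximal treadmill test, all recorded as 15-s mean HR/VO2 samples.

Latent physiology per individual
--------------------------------
Each profile carries a true linear HR-VO2 relationship per modality,
anchored so that HR equals the resting HR at the modality's resting VO2
and the test-family maximal HR at VO2max.  Walking is given a higher
oxygen pulse than cycling: its true line is the cycling line scaled by
(1 + walking_offset_pct/100), i.e. VO2 is raised by a fixed percentage at
matched HR (equivalently, HR is lowered at matched VO2).  The offset
defaults to 8%, inside the 5-12% band of differences the method detects
in practice.

Noise model
-----------
Two scales per signal: a per-workload *level* offset (``hr_noise_sd``,
``vo2_noise_sd``) perturbing the steady-state target — the noise that
propagates into calibration points — and a small within-recording
per-sample noise (``hr_sample_sd``, ``vo2_sample_sd``) reflecting that
15-s means of heart rate are strongly autocorrelated and therefore vary
far less sample-to-sample than between workloads.  Approach to steady
state is exponential with time constant ``tau_s``.

All constants not anchored in published group values are documented
simulator conventions, configurable in :class:`CohortConfig`.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigError, ValidationError
from .types import SAMPLE_INTERVAL_S, Recording, Workload


@dataclass(frozen=True)
class SyntheticProfile:
    """Latent physiology of one simulated participant."""

    participant_id: str
    sex: str
    mass: float                  # kg
    hr_rest: float               # beats/min
    hr_max_treadmill: float      # beats/min
    hr_max_cycle: float          # beats/min
    vo2max_per_kg: float         # mL/kg/min
    lines: dict                  # modality -> (intercept L/min, slope L/min per bpm)
    walking_offset_pct: float
    hr_noise_sd: float
    vo2_noise_sd: float
    hr_sample_sd: float
    vo2_sample_sd: float
    tau_s: float

    @property
    def vo2max_l_min(self) -> float:
        return self.vo2max_per_kg * self.mass / 1000.0

    @property
    def vo2_rest_l_min(self) -> float:
        return 3.5 * self.mass / 1000.0

    def hr_at_vo2(self, modality: str, vo2: float) -> float:
        a, b = self.lines[modality]
        return (vo2 - a) / b


@dataclass
class CohortConfig:
    """Distribution parameters and protocol grids for cohort simulation.

    Anthropometric and resting-HR distributions follow the reference
    study's group values; VO2max means are the study's running values by
    sex.  The treadmill maximal HR mean (184.8) is the value implied by
    the group %HRR anchors together with the mean resting HR.
    """

    n_women: int = 12
    n_men: int = 12
    seed: int = 0

    mass_mean_women: float = 60.0
    mass_sd_women: float = 5.3
    mass_mean_men: float = 80.8
    mass_sd_men: float = 9.3
    hr_rest_mean: float = 50.6
    hr_rest_sd: float = 6.5
    vo2max_mean_women: float = 50.4
    vo2max_mean_men: float = 59.1
    vo2max_sd: float = 5.0
    hr_max_treadmill_mean: float = 184.8
    hr_max_treadmill_sd: float = 9.0
    # cycling maximal HR runs a few beats below the treadmill value
    hr_max_cycle_deficit_mean: float = 5.0
    hr_max_cycle_deficit_sd: float = 3.0

    walking_offset_pct: float = 8.0

    hr_noise_sd: float = 2.0      # per-workload HR level offset, bpm
    vo2_noise_sd: float = 0.03    # per-workload VO2 level offset, L/min
    hr_sample_sd: float = 0.5     # within-recording 15-s noise, bpm
    vo2_sample_sd: float = 0.02   # within-recording 15-s noise, L/min
    tau_s: float = 40.0           # exponential approach time constant, s

    cycle_watts: tuple = (50.0, 75.0, 100.0, 125.0, 150.0)
    walk_speeds_kmh: tuple = (3.0, 4.0, 5.0, 6.0, 7.0)
    run_speeds_kmh: tuple = (6.0, 7.0, 8.0, 10.0, 12.0)

    # energy-cost conventions (see true_vo2)
    k_cycle: float = 0.0116       # L/min per W
    c_cycle: float = 0.0035       # L/min per kg (unloaded cycling + rest)
    walk_linear: float = 0.1      # mL/kg/min per m/min
    walk_quad: float = 0.0046     # mL/kg/min per (m/min)^2 above onset
    walk_quad_onset_m_min: float = 83.3   # ~5 km/h; brisk-walking economy term
    run_linear: float = 0.2       # mL/kg/min per m/min
    rest_vo2_mlkg: float = 3.5    # resting metabolic rate, mL/kg/min

    submax_duration_s: float = 360.0
    max_duration_s: float = 300.0
    rest_duration_s: float = 1800.0

    def __post_init__(self):
        for name in ("mass_sd_women", "mass_sd_men", "hr_rest_sd", "vo2max_sd",
                     "hr_max_treadmill_sd", "hr_max_cycle_deficit_sd",
                     "hr_noise_sd", "vo2_noise_sd", "hr_sample_sd",
                     "vo2_sample_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.tau_s < 0:
            raise ConfigError("tau_s must be >= 0")
        if self.n_women < 0 or self.n_men < 0 or self.n_women + self.n_men == 0:
            raise ConfigError("cohort must contain at least one participant")
        for name in ("cycle_watts", "walk_speeds_kmh", "run_speeds_kmh"):
            if len(getattr(self, name)) == 0:
                raise ConfigError(f"{name} grid must be non-empty")
        if not 0 <= self.walking_offset_pct <= 15:
            raise ConfigError("walking_offset_pct must be within 0-15")
        if self.submax_duration_s < 300:
            raise ConfigError("submax_duration_s must be >= 300 s")

    def noise_free(self) -> "CohortConfig":
        """Copy with all randomness and dynamics removed (degenerate draws)."""
        return replace(self, mass_sd_women=0.0, mass_sd_men=0.0,
                       hr_rest_sd=0.0, vo2max_sd=0.0, hr_max_treadmill_sd=0.0,
                       hr_max_cycle_deficit_sd=0.0, hr_noise_sd=0.0,
                       vo2_noise_sd=0.0, hr_sample_sd=0.0, vo2_sample_sd=0.0,
                       tau_s=0.0)


def true_vo2(modality: str, workload, mass: float,
             config: CohortConfig | None = None) -> float:
    """Steady-state oxygen cost (L/min) of a workload.

    Cycling: k * watts + c * mass.  Walking: standard linear cost in
    speed plus a quadratic brisk-walking term above ~5 km/h (walking
    economy deteriorates sharply near the walk-run transition).  Running:
    standard linear cost in speed.  All constants are simulator
    conventions exposed on :class:`CohortConfig`.
    """
    cfg = config or _DEFAULT_CONFIG
    if isinstance(workload, Workload):
        value = workload.watts if modality == "cycle" else workload.speed_kmh
    else:
        value = float(workload)
    if value is None or value < 0:
        raise ValidationError(f"invalid workload {workload!r} for {modality}")
    if modality == "cycle":
        return cfg.k_cycle * value + cfg.c_cycle * mass
    speed_m_min = value * 1000.0 / 60.0
    if modality == "walk":
        per_kg = (cfg.rest_vo2_mlkg + cfg.walk_linear * speed_m_min
                  + cfg.walk_quad
                  * max(0.0, speed_m_min - cfg.walk_quad_onset_m_min) ** 2)
    elif modality == "run":
        per_kg = cfg.rest_vo2_mlkg + cfg.run_linear * speed_m_min
    else:
        raise ValidationError(f"unknown modality {modality!r}")
    return per_kg * mass / 1000.0


_DEFAULT_CONFIG = CohortConfig()


def sample_cohort(config: CohortConfig,
                  rng: np.random.Generator | None = None) -> list[SyntheticProfile]:
    """Draw a cohort of latent physiological profiles.

    Deterministic for a fixed config seed.  Per-modality true lines are
    derived from each individual's resting and maximal anchors; the
    walking line is the cycling line scaled by (1 + offset/100).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    profiles = []
    sexes = ["F"] * config.n_women + ["M"] * config.n_men
    for i, sex in enumerate(sexes):
        if sex == "F":
            mass = rng.normal(config.mass_mean_women, config.mass_sd_women)
            vo2max = rng.normal(config.vo2max_mean_women, config.vo2max_sd)
        else:
            mass = rng.normal(config.mass_mean_men, config.mass_sd_men)
            vo2max = rng.normal(config.vo2max_mean_men, config.vo2max_sd)
        hr_rest = rng.normal(config.hr_rest_mean, config.hr_rest_sd)
        hr_max_tread = rng.normal(config.hr_max_treadmill_mean,
                                  config.hr_max_treadmill_sd)
        deficit = max(0.0, rng.normal(config.hr_max_cycle_deficit_mean,
                                      config.hr_max_cycle_deficit_sd))
        # guard implausible tail draws without distorting the bulk
        mass = max(mass, 35.0)
        vo2max = max(vo2max, 25.0)
        hr_max_tread = max(hr_max_tread, hr_rest + 60.0)
        hr_max_cycle = hr_max_tread - deficit

        vo2_rest = config.rest_vo2_mlkg * mass / 1000.0
        vo2max_l = vo2max * mass / 1000.0
        b_cyc = (vo2max_l - vo2_rest) / (hr_max_cycle - hr_rest)
        a_cyc = vo2_rest - b_cyc * hr_rest
        b_run = (vo2max_l - vo2_rest) / (hr_max_tread - hr_rest)
        a_run = vo2_rest - b_run * hr_rest
        scale = 1.0 + config.walking_offset_pct / 100.0
        lines = {
            "cycle": (a_cyc, b_cyc),
            "run": (a_run, b_run),
            "walk": (scale * a_cyc, scale * b_cyc),
        }
        profiles.append(SyntheticProfile(
            participant_id=f"P{i + 1:02d}",
            sex=sex,
            mass=float(mass),
            hr_rest=float(hr_rest),
            hr_max_treadmill=float(hr_max_tread),
            hr_max_cycle=float(hr_max_cycle),
            vo2max_per_kg=float(vo2max),
            lines=lines,
            walking_offset_pct=config.walking_offset_pct,
            hr_noise_sd=config.hr_noise_sd,
            vo2_noise_sd=config.vo2_noise_sd,
            hr_sample_sd=config.hr_sample_sd,
            vo2_sample_sd=config.vo2_sample_sd,
            tau_s=config.tau_s,
        ))
    return profiles


def _approach(target: float, prev: float, t: np.ndarray, tau: float) -> np.ndarray:
    if tau <= 0.0:
        return np.full(t.shape, target)
    return target - (target - prev) * np.exp(-t / tau)


def _noisy(values: np.ndarray, sd: float, rng: np.random.Generator,
           floor: float | None = None) -> np.ndarray:
    if sd > 0:
        values = values + rng.normal(0.0, sd, size=values.shape)
    if floor is not None:
        values = np.maximum(values, floor)
    return values


def simulate_recording(profile: SyntheticProfile, modality: str, workload,
                       duration_s: float, rng: np.random.Generator,
                       config: CohortConfig | None = None,
                       prev_hr: float | None = None,
                       prev_vo2: float | None = None,
                       occasion: int = 2,
                       phase: str = "submax") -> Recording:
    """Simulate one submaximal workload's 15-s series.

    Steady-state targets come from the modality's true line at the
    workload's oxygen cost, perturbed by per-workload level noise; samples
    approach the target exponentially from the previous state and carry
    independent per-sample noise.
    """
    cfg = config or _DEFAULT_CONFIG
    if duration_s < 300:
        raise ValidationError("duration_s must be >= 300 s")
    vo2_ss = true_vo2(modality, workload, profile.mass, cfg)
    hr_ss = profile.hr_at_vo2(modality, vo2_ss)
    # physiological ceilings: neither HR nor VO2 can exceed the
    # individual's maxima, however demanding the workload
    hr_ceiling = (profile.hr_max_cycle if modality == "cycle"
                  else profile.hr_max_treadmill)
    hr_ss = min(hr_ss, hr_ceiling)
    vo2_ss = min(vo2_ss, profile.vo2max_l_min)
    if profile.hr_noise_sd > 0:
        hr_ss += rng.normal(0.0, profile.hr_noise_sd)
    if profile.vo2_noise_sd > 0:
        vo2_ss += rng.normal(0.0, profile.vo2_noise_sd)
    if prev_hr is None:
        prev_hr = profile.hr_rest
    if prev_vo2 is None:
        prev_vo2 = profile.vo2_rest_l_min

    n = int(duration_s // SAMPLE_INTERVAL_S)
    t_start = np.arange(n) * SAMPLE_INTERVAL_S
    t_eval = t_start + SAMPLE_INTERVAL_S
    hr = _approach(hr_ss, prev_hr, t_eval, profile.tau_s)
    vo2 = _approach(vo2_ss, prev_vo2, t_eval, profile.tau_s)
    hr = _noisy(hr, profile.hr_sample_sd, rng, floor=1.0)
    vo2 = _noisy(vo2, profile.vo2_sample_sd, rng, floor=0.0)

    frac = min(vo2_ss / profile.vo2max_l_min, 1.0)
    rpe = int(np.clip(round(6 + 13 * frac), 6, 20))
    if isinstance(workload, Workload):
        wl = workload
    elif modality == "cycle":
        wl = Workload(label=f"{workload:g}W", watts=float(workload))
    else:
        wl = Workload(label=f"{workload:g}km/h", speed_kmh=float(workload),
                      incline_deg=0.0)
    return Recording(
        participant_id=profile.participant_id, occasion=occasion,
        modality=modality, workload=wl, t_start=t_start, hr=hr, vo2=vo2,
        phase=phase, rpe_legs=rpe, rpe_breath=rpe,
    )


def _simulate_maximal(profile: SyntheticProfile, modality: str,
                      rng: np.random.Generator, cfg: CohortConfig,
                      prev_hr: float, prev_vo2: float,
                      occasion: int) -> Recording:
    """Ramp to the test family's maxima with a final one-minute plateau."""
    hr_max = profile.hr_max_cycle if modality == "cycle" else profile.hr_max_treadmill
    vo2_max = profile.vo2max_l_min
    if profile.hr_noise_sd > 0:
        hr_max += rng.normal(0.0, profile.hr_noise_sd)
    if profile.vo2_noise_sd > 0:
        vo2_max += rng.normal(0.0, profile.vo2_noise_sd)
    n = int(cfg.max_duration_s // SAMPLE_INTERVAL_S)
    # VO2 plateaus over the final two minutes (increment 0.1 L/min < the
    # 150 mL/min criterion) while HR still creeps to its maximum
    plateau_gap = 0.1
    n_ramp = n - 8
    hr = np.concatenate([
        np.linspace(prev_hr, hr_max, n - 4, endpoint=False),
        np.full(4, hr_max),
    ])
    vo2 = np.concatenate([
        np.linspace(prev_vo2, vo2_max - plateau_gap, n_ramp, endpoint=False),
        np.full(4, vo2_max - plateau_gap),
        np.full(4, vo2_max),
    ])
    hr = _noisy(hr, profile.hr_sample_sd, rng, floor=1.0)
    vo2 = _noisy(vo2, profile.vo2_sample_sd, rng, floor=0.0)
    rer = float(rng.normal(1.15, 0.03)) if profile.vo2_noise_sd > 0 else 1.15
    label = "max_cycle_ramp" if modality == "cycle" else "max_incline_run"
    wl = Workload(label=label)
    return Recording(
        participant_id=profile.participant_id, occasion=occasion,
        modality=modality, workload=wl,
        t_start=np.arange(n) * SAMPLE_INTERVAL_S, hr=hr, vo2=vo2,
        phase="maximal", rpe_legs=19, rpe_breath=18, rer=rer,
    )


def simulate_study(cohort: list[SyntheticProfile],
                   config: CohortConfig) -> list[Recording]:
    """Simulate the full four-occasion study for a cohort.

    Occasion 1: 30-min supine rest.  Occasion 2: five cycling workloads
    plus the maximal cycle ramp.  Occasion 3: five walking speeds.
    Occasion 4: five running speeds plus the maximal treadmill test.
    Submaximal workloads within an occasion run uninterrupted, each
    starting from the previous workload's state.  Every recording draws
    from its own seeded substream, so datasets are reproducible while
    recordings stay independent.
    """
    if not cohort:
        raise ValidationError("cohort must be non-empty")
    root = np.random.SeedSequence((config.seed, 1))
    recordings: list[Recording] = []
    for profile, child in zip(cohort, root.spawn(len(cohort))):
        streams = [np.random.default_rng(s) for s in child.spawn(20)]
        it = iter(streams)

        rest_rng = next(it)
        n_rest = int(config.rest_duration_s // SAMPLE_INTERVAL_S)
        hr = _noisy(np.full(n_rest, profile.hr_rest), profile.hr_sample_sd,
                    rest_rng, floor=1.0)
        vo2 = _noisy(np.full(n_rest, profile.vo2_rest_l_min),
                     profile.vo2_sample_sd, rest_rng, floor=0.0)
        recordings.append(Recording(
            participant_id=profile.participant_id, occasion=1, modality=None,
            workload=Workload(label="rest"),
            t_start=np.arange(n_rest) * SAMPLE_INTERVAL_S, hr=hr, vo2=vo2,
            phase="rest",
        ))

        plans = [
            ("cycle", config.cycle_watts, 2, True),
            ("walk", config.walk_speeds_kmh, 3, False),
            ("run", config.run_speeds_kmh, 4, True),
        ]
        for modality, grid, occasion, has_max in plans:
            prev_hr, prev_vo2 = profile.hr_rest, profile.vo2_rest_l_min
            for wl in grid:
                rec = simulate_recording(
                    profile, modality, wl, config.submax_duration_s, next(it),
                    config, prev_hr=prev_hr, prev_vo2=prev_vo2,
                    occasion=occasion, phase="submax")
                recordings.append(rec)
                prev_hr, prev_vo2 = float(rec.hr[-1]), float(rec.vo2[-1])
            if has_max:
                # ~10 min rest, then light exercise before the ramp
                light_vo2 = profile.vo2_rest_l_min + 0.3 * (
                    profile.vo2max_l_min - profile.vo2_rest_l_min)
                light_hr = profile.hr_at_vo2(modality, light_vo2)
                recordings.append(_simulate_maximal(
                    profile, modality, next(it), config,
                    prev_hr=light_hr, prev_vo2=light_vo2, occasion=occasion))
    return recordings
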