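# Methods

## The heart-rate method

Oxygen uptake (V̇O₂, L·min⁻¹) rises linearly with heart rate (HR,
beats·min⁻¹) across submaximal steady-state exercise, but the line differs
between individuals and, more subtly, between exercise modalities.  The
package implements the full estimation pipeline:

1. **Signal extraction.** Raw recordings are 15-s means of paired HR and
   V̇O₂.  Resting HR is the mean of the last 5 min of a 30-min supine
   rest.  A submaximal workload contributes a calibration point only if a
   steady state exists: a window of two consecutive minutes (8 samples)
   with HR range (max − min) ≤ 3 beats·min⁻¹; the point averages the
   *last* minute of the last such window.  Maximal HR and V̇O₂ are the
   means of the one-minute window with the highest continuous paired
   values (V̇O₂-maximising by default; HR-maximising via config).  A
   maximal test is valid when at least two of three criteria hold: V̇O₂
   plateau (final-minute increment < 150 mL·min⁻¹), RER ≥ 1.10,
   RPE ≥ 17.  Missing criterion values count as not met.
2. **Calibration.** Per participant and modality, V̇O₂ is regressed on HR
   by OLS: model 1 from the five submaximal points; model 2 adds exactly
   one maximal point — the cycling maximum for cycling, the treadmill
   (running) maximum for both walking and running.  Walking has no
   maximal test of its own, so its model 2 borrows the treadmill point.
   The maximal point is not weighted.  Non-positive slopes warn but do
   not fail (they occur in pathological or degenerate data).
3. **Intensity anchoring.** %HRR = (HR − HRrest)/(HRmax − HRrest)·100,
   with HRmax always the treadmill value and HRrest the first-occasion
   rest.  HR targets at the seven ACSM levels (25–85 %HRR) are the exact
   inverse; V̇O₂ estimates follow from the calibration line.  Because two
   affine maps compose, estimates are exactly affine in the level —
   asserted, not approximated.  Estimates below zero or outside the
   calibrated HR range are flagged, never suppressed: they matter for
   interchangeability even where not practically applicable.
4. **Group analysis.** Pairwise modality contrasts (walk−cycle,
   run−cycle, run−walk) and model contrasts are evaluated on
   per-individual differences, absolute (L·min⁻¹) and relative (% of the
   reference individual's value — computed per individual, then
   averaged, which is what reproduces the published SDs of relative
   differences).  A two-sided one-sample t-test (df = n−1) tests the
   mean against zero; since every value enters two comparisons, raw
   p-values are doubled and capped at 1 (p_adj), with significance at
   p_adj < 0.05 and stars at 0.05/0.01/0.001.  Pooled V̇O₂-on-%HRR
   regressions and line-of-identity regressions (statsmodels OLS with
   95% coefficient CIs) summarise interchangeability; for balanced
   grids the pooled coefficients coincide exactly with a regression on
   the per-level means, which is what lets published group slopes be
   recovered from printed means alone.

## Synthetic cohorts

Individual-level data for this design are not publicly available, so the
generator produces cohorts with the design's statistical structure.

**Anchors.** Mass ~ N(60.0, 5.3) kg (women) / N(80.8, 9.3) (men);
HRrest ~ N(50.6, 6.5); V̇O₂max ~ N(50.4, 5) / N(59.1, 5) mL·kg⁻¹·min⁻¹;
treadmill HRmax ~ N(184.8, 9), the mean being the value implied by the
group %HRR anchors; cycling HRmax sits N(5, 3) beats lower.  Each
modality's true line joins (HRrest, resting V̇O₂ = 3.5·mass/1000) to
(HRmax of the test family, V̇O₂max).  Walking's higher oxygen pulse is
injected by scaling the cycling line by (1 + offset/100), offset 8% by
default (configurable 0–15%): V̇O₂ is raised by exactly that percentage
at every matched HR, so in a noise-free run the walk-vs-cycle relative
differences recover the offset exactly at all levels (model 1).

**Energy costs** (simulator conventions, configurable): cycling
0.0116·W + 0.0035·mass L·min⁻¹; running mass·(0.2·s + 3.5)/1000 with s
in m·min⁻¹; walking mass·(0.1·s + 3.5 + 0.0046·max(0, s−83.3)²)/1000.
The quadratic term reflects the steep deterioration of walking economy
above ~5 km·h⁻¹; with it, the default cohort's walking workloads span
roughly 16–37% of V̇O₂max, cycling ~25–60% and running ~45–85%,
matching the intensity spectra this protocol produces.  Steady-state
targets saturate at the individual's maxima (HR cannot exceed HRmax);
the real protocol individualises top running speeds, which the simulator
does not, so very unfit draws run close to their ceiling.

**Dynamics and noise.** Samples approach the steady-state target
exponentially (τ = 40 s) from the previous workload's state — workloads
run uninterrupted within an occasion — so steady state is reached well
inside the 6-min workload, as in practice.  Noise has two scales per
signal: a per-workload *level* offset (HR 2.0 bpm, V̇O₂ 0.03 L·min⁻¹)
perturbing the target — the noise that propagates into calibration
points and drives every power property — and a small per-sample noise
(HR 0.5 bpm, V̇O₂ 0.02 L·min⁻¹) reflecting that 15-s means of HR are
strongly autocorrelated.  The split is deliberate: i.i.d. 2-bpm noise on
individual samples would make the 2–3-bpm steady-state criterion almost
never pass, which real recordings plainly do.  Maximal tests ramp to the
individual's maxima with a final two-minute V̇O₂ plateau (increment
100 mL·min⁻¹), RER ~ N(1.15, 0.03), RPE 18–19, so validity criteria are
satisfiable and genuinely computed.  One global seed spawns per-recording
substreams: datasets are reproducible, recordings independent.

**What the generator does not emulate.** Inter-individual variation in
the walking offset (fixed at 8% for everyone, so simulated
relative-difference SDs reflect measurement noise only and are smaller
than real between-subject spreads); day-to-day drift shared across a
session; RER computed from gas fractions; breath-by-breath dynamics;
randomised occasion order.  Passing tests therefore demonstrate the
pipeline's correctness and its operating characteristics under this
noise model, not field validity.

## Numerical choices and edge cases

* Steady-state threshold defaults to the permissive 3 beats·min⁻¹ (the
  criterion is quoted as 2–3); the stricter reading is one config key
  away.  The window statistic is max − min, not drift between minute
  means.
* `max_values` ties resolve to the later window (maximal effort occurs at
  test end); exact float ties only.
* Identical differences in a paired comparison make the t statistic
  undefined: a zero mean is reported as p = 1, a non-zero mean as p = 0.
* Zero reference values are excluded from relative differences with a
  warning; the absolute statistics keep the full n.
* Recordings CSVs are written with 17 significant digits and parsed with
  round-trip float precision, so write → read is bit-exact.
* Report tables round only at render time: V̇O₂ two decimals, slopes
  four, percentages one; raw outputs keep full precision.

## Problem sizes

Replicated experiments use the study's own size (n = 24) throughout:
detection power for the walking offset uses 200 independently seeded
replicates of the full pipeline (simulate → extract → calibrate →
estimate → test); identity-r² medians use 100 cohorts.  A single
replicate takes ~0.15 s, so the full experiment suite runs in well under
a minute.

## Known limitations

* Per-workload HR level noise is horizontal (errors-in-variables), so
  model-1 slopes attenuate slightly where the calibrated HR span is
  narrow (walking); the injected 8% offset is recovered as ~6–7% at
  moderate levels, mirroring how such attenuation would act on real
  calibrations.
* Walking model 2 borrows the treadmill maximal point, which lies on the
  running line, below the walking line's extrapolation; the walking
  model-2 line therefore rotates toward the cycling scale.  This is a
  faithful consequence of the study design combined with the simulator's
  single-offset walking model, and it is why exact-recovery checks are
  stated for model 1.
* There is no dedicated sex-stratified testing mode (the design found no
  systematic sex differences in the mode contrasts); stratified analyses
  are run by filtering the estimate grid to one sex before calling the
  comparison functions.
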