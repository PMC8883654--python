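"""Published group-level summary values from the reference laboratory study.

The study (24 physically active adults, 12 women and 12 men) established
individual HR-VO2 calibrations in ergometer cycling, level treadmill
walking and running, and estimated VO2 at the seven ACSM %HRR levels with
model 1 (five submaximal workloads) and model 2 (plus one maximal
workload).  Individual data are unpublished; the printed group summaries
below serve as inputs for consistency checks that are mathematically
forced by the printed values (balanced-design pooling, linearity of the
mean, affinity of the %HRR scale).

All VO2 values are L/min; HR values are beats/min.
"""
from __future__ import annotations

#: %HRR levels at which VO2 was estimated
LEVELS = (25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0)

#: group mean HR targets at each level (identical for both models)
GROUP_HR_MEAN = (84.1, 97.6, 111.0, 124.4, 137.9, 151.3, 164.7)

#: group mean estimated VO2 per (model, modality) across the seven levels
GROUP_VO2_MEAN = {
    (1, "cycle"): (0.88, 1.25, 1.62, 1.98, 2.35, 2.72, 3.09),
    (1, "walk"):  (0.96, 1.34, 1.72, 2.10, 2.48, 2.86, 3.25),
    (1, "run"):   (1.00, 1.34, 1.69, 2.03, 2.37, 2.72, 3.06),
    (2, "cycle"): (0.84, 1.23, 1.61, 2.00, 2.39, 2.78, 3.17),
    (2, "walk"):  (0.95, 1.34, 1.73, 2.12, 2.52, 2.91, 3.30),
    (2, "run"):   (0.86, 1.25, 1.64, 2.03, 2.42, 2.81, 3.21),
}

#: printed slopes of the pooled VO2-on-%HRR regressions (L/min per %HRR)
GROUP_SLOPES = {
    (1, "cycle"): 0.0368,
    (1, "walk"): 0.0381,
    (1, "run"): 0.0343,
    (2, "cycle"): 0.0389,
    (2, "walk"): 0.0391,
    (2, "run"): 0.0391,
}

#: printed r² of the line-of-identity modality comparisons
IDENTITY_MODE_R2 = {
    (1, "walk", "cycle"): 0.913,
    (2, "walk", "cycle"): 0.965,
    (1, "run", "cycle"): 0.952,
    (2, "run", "cycle"): 0.975,
    (1, "run", "walk"): 0.933,
    (2, "run", "walk"): 0.967,
}

#: group resting HR (all participants) and derived treadmill maximal HR
HR_REST_MEAN = 50.6
HR_MAX_TREADMILL_MEAN = 184.8
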