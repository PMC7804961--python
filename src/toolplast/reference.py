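"""Published reference values for the developmental tool-use cohort.

The original study (90 participants aged 7.5-21.5, data archived at
https://osf.io/3g9mz/) reported per-puberty-score cohort characteristics,
per-parameter crossing points of the PRE/POST free-hand curves, explained
variances of the component PCAs, and the linear-vs-quadratic likelihood-ratio
statistics.  These numbers serve two purposes here:

* the synthetic-data generator uses the per-score cohort table as its default
  marginals, so simulated cohorts match the published sample structure;
* :func:`toolplast.pipeline.reproduce_study` compares a re-analysis of the
  archived data against the published values at documented tolerances.
"""

from __future__ import annotations

import pandas as pd

#: The nine trial-level kinematic parameters, in canonical order.
PARAMETERS = (
    "acc_latency",
    "acc_amplitude",
    "vel_latency",
    "vel_amplitude",
    "dec_latency",
    "dec_amplitude",
    "mga_latency",
    "mga",
    "movement_time",
)

#: Transport-phase (reaching) parameters: wrist acceleration, velocity and
#: deceleration peak latencies and amplitudes.
REACHING_PARAMETERS = PARAMETERS[:6]

#: Grip-formation (grasping) parameters: maximum grip aperture and its latency.
GRASPING_PARAMETERS = ("mga_latency", "mga")

# Per-puberty-score cohort characteristics of the published sample:
# sample size, sex split, and mean age (years), height (cm), forearm length
# (cm) and gesture-imitation score (/72).
_COHORT_ROWS = [
    #  PS   n   F   M   age  height forearm imitation
    (5, 4, 1, 3, 9.7, 144.0, 19.1, 49.7),
    (6, 6, 2, 4, 9.6, 133.0, 19.8, 52.7),
    (7, 7, 4, 3, 10.0, 140.0, 20.2, 54.1),
    (8, 7, 2, 5, 11.0, 144.0, 21.1, 54.7),
    (9, 8, 3, 5, 12.1, 153.0, 22.2, 57.3),
    (10, 4, 1, 3, 11.5, 143.0, 21.3, 58.3),
    (11, 5, 3, 2, 13.5, 160.0, 23.6, 56.2),
    (12, 3, 2, 1, 13.1, 160.0, 24.5, 56.3),
    (13, 2, 2, 0, 12.6, 158.0, 24.0, 60.0),
    (14, 4, 1, 3, 14.8, 168.0, 24.7, 60.5),
    (15, 8, 5, 3, 14.6, 167.0, 24.7, 62.1),
    (16, 3, 2, 1, 15.9, 172.0, 25.5, 59.0),
    (17, 6, 4, 2, 15.3, 171.0, 25.3, 48.0),
    (18, 3, 2, 1, 15.7, 165.0, 23.5, 60.0),
    (19, 11, 9, 2, 17.8, 165.0, 24.4, 59.9),
    (20, 9, 3, 6, 19.8, 172.0, 25.0, 61.5),
]

COHORT_TABLE = pd.DataFrame(
    _COHORT_ROWS,
    columns=[
        "puberty_score",
        "n",
        "n_female",
        "n_male",
        "age_mean",
        "height_mean",
        "forearm_mean",
        "imitation_mean",
    ],
).set_index("puberty_score")

#: Published per-score sample counts (sum to 90) used as default sampling
#: weights for synthetic cohorts.
PUBERTY_SCORE_COUNTS = {ps: int(n) for ps, n in COHORT_TABLE["n"].items()}

#: Published Pearson correlation between participant height and forearm length.
HEIGHT_FOREARM_R = 0.89

#: Free-hand PRE/POST crossing points on the puberty axis and the interval of
#: equivalence (integer bounds) published for each kinematic parameter.
REPORTED_CROSSINGS = {
    "acc_latency": (12.45, 5, 17),
    "acc_amplitude": (17.23, 16, 18),
    "vel_latency": (16.24, 14, 17),
    "vel_amplitude": (17.54, 16, 19),
    "dec_latency": (14.29, 11, 17),
    "dec_amplitude": (16.71, 15, 18),
    "mga_latency": (16.71, 15, 18),
    "mga": (18.02, 17, 19),
    "movement_time": (12.15, 10, 15),
}

#: Published overall crossing summaries: meta-parameter crossing with its
#: interval, plus the mean and median across the nine parameters.
REPORTED_META_CROSSING = (16.0, 14, 17)
REPORTED_MEAN_CROSSING = 15.7
REPORTED_MEDIAN_CROSSING = 16.7

#: Published first-component explained variances (percent).
REPORTED_EXPLAINED_VARIANCE = {
    ("freehand", "reaching"): 66.2,
    ("freehand", "grasping"): 62.3,
    ("tooluse", "reaching"): 60.9,
    ("tooluse", "grasping"): 60.4,
}

#: Published quadratic-vs-linear likelihood-ratio statistics (chi-square, 2 df)
#: for the meta-parameter of each task.
REPORTED_LRT_CHI2 = {
    "freehand": 7.28,
    "tooluse": 3.03,
    "armlength": 11.26,
}

#: Published arm-length-estimation crossing point and equivalence interval.
REPORTED_ARMLENGTH_CROSSING = (7.5, 6, 8)

#: Default tolerances for the reproduction comparison.
REPRODUCE_TOLERANCES = {
    "crossing_point": 0.05,
    "explained_variance_pct": 0.5,
    "lrt_chi2": 0.05,
    "correlation": 0.01,
}
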