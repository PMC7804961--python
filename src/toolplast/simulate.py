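"""Synthetic cohorts, trial-level kinematic parameters and marker trajectories.

The generator mirrors the statistical structure assumed by the analysis
stages: a cohort of subjects with puberty scores on the 5-20 scale, subject
random intercepts, trial-level Gaussian noise, and a session-by-puberty
interaction whose POST-PRE difference function can be pinned to cross zero at
a configurable puberty value (the "target crossing").  Full 200 Hz marker
trajectories embed each trial's parameters in a minimum-jerk wrist path plus
a raised-cosine grip-aperture profile, so the kinematic extraction stage can
be tested end to end against analytic ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import minjerk
from .reference import COHORT_TABLE, PARAMETERS, PUBERTY_SCORE_COUNTS

__all__ = [
    "Subject",
    "EffectSpec",
    "TrialRecording",
    "generate_cohort",
    "cohort_frame",
    "generate_trial_parameters",
    "generate_trajectories",
    "generate_armlength_trials",
    "generate_imitation_scores",
    "default_effect_specs",
    "pivot_trials",
    "write_recording",
    "read_recording",
]

PUBERTY_MIN, PUBERTY_MAX = 5, 20

#: Tool lengths (cm) assigned by participant height, following the published
#: sizing rule: <= 122 cm -> 25 cm tool, 123-146 cm -> 32 cm, >= 147 cm -> 40.
TOOL_LENGTHS = (25.0, 32.0, 40.0)


@dataclass(frozen=True)
class Subject:
    """One participant of a (synthetic) cohort."""

    subject_id: str
    puberty_score: int
    sex: str
    age: float
    height: float
    forearm_length: float
    handedness: str
    tool_length: float

    def __post_init__(self):
        if not PUBERTY_MIN <= self.puberty_score <= PUBERTY_MAX:
            raise ValueError(f"puberty_score {self.puberty_score} outside [5, 20]")
        if self.forearm_length <= 0:
            raise ValueError("forearm_length must be positive")
        if self.tool_length not in TOOL_LENGTHS:
            raise ValueError(f"tool_length must be one of {TOOL_LENGTHS}")


def _poly_eval(coeffs: Sequence[float], x):
    """Evaluate c0 + c1 x + c2 x^2 ... (ascending coefficients)."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    for power, c in enumerate(coeffs):
        out = out + c * np.asarray(x, dtype=float) ** power
    return out


@dataclass(frozen=True)
class EffectSpec:
    """Generative fixed/random-effect specification for one parameter.

    Trial values follow

        y = baseline + b_subj + session_main * s + f(puberty) + g(puberty) * s + eps

    with session contrast ``s`` = -1/2 (PRE) / +1/2 (POST),
    ``b_subj ~ N(0, subject_sd^2)`` and ``eps ~ N(0, residual_sd^2)``.
    ``puberty_curve`` (f) and ``interaction_curve`` (g) are ascending
    polynomial coefficients of degree <= 2 on the raw puberty scale.

    When ``target_crossing`` is set, the constant term of g is adjusted so
    that the population POST-PRE difference ``session_main + g(puberty)`` is
    exactly zero at that puberty value.
    """

    baseline: float
    session_main: float = 0.0
    puberty_curve: tuple = (0.0,)
    interaction_curve: tuple = (0.0,)
    subject_sd: float = 0.0
    residual_sd: float = 0.0
    target_crossing: float | None = None

    def __post_init__(self):
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if len(self.puberty_curve) > 3 or len(self.interaction_curve) > 3:
            raise ValueError("puberty polynomials are limited to degree 2")
        if self.target_crossing is not None:
            g = list(self.interaction_curve) + [0.0] * (3 - len(self.interaction_curve))
            c = float(self.target_crossing)
            g[0] = -(self.session_main + g[1] * c + g[2] * c * c)
            object.__setattr__(self, "interaction_curve", tuple(g))

    def mean(self, puberty, session_contrast):
        """Population mean at a puberty value and session contrast (+-1/2)."""
        p = np.asarray(puberty, dtype=float)
        return (
            self.baseline
            + self.session_main * session_contrast
            + _poly_eval(self.puberty_curve, p)
            + _poly_eval(self.interaction_curve, p) * session_contrast
        )

    def difference(self, puberty):
        """Population POST - PRE difference at a puberty value."""
        return self.session_main + _poly_eval(self.interaction_curve, puberty)


@dataclass
class TrialRecording:
    """Raw marker time series for one reach-to-grasp trial.

    Positions are in millimetres, times in seconds; ``ground_truth`` holds the
    analytic values of the extraction estimands embedded by the generator.
    """

    subject_id: str
    condition: str
    trial_index: int
    times: np.ndarray
    wrist: np.ndarray
    thumb: np.ndarray
    index: np.ndarray
    switch_release_time: float
    sampling_rate: float
    ground_truth: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.times)
        for name in ("wrist", "thumb", "index"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must be (n, 3) matching sample_times")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if not (self.times[0] <= self.switch_release_time <= self.times[-1]):
            raise ValueError("switch_release_time outside recorded span")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _within_score_correlation(weights: dict, height_sd: float, forearm_sd: float,
                              target_r: float) -> float:
    """Within-score height/forearm correlation that yields the target overall
    correlation given the between-score spread of the per-score means."""
    scores = np.array(sorted(weights))
    w = np.array([weights[s] for s in scores], dtype=float)
    w = w / w.sum()
    mu_h = COHORT_TABLE.loc[scores, "height_mean"].to_numpy()
    mu_f = COHORT_TABLE.loc[scores, "forearm_mean"].to_numpy()
    eh = w @ mu_h
    ef = w @ mu_f
    var_bh = w @ (mu_h - eh) ** 2
    var_bf = w @ (mu_f - ef) ** 2
    cov_b = w @ ((mu_h - eh) * (mu_f - ef))
    cov_target = target_r * math.sqrt((var_bh + height_sd**2) * (var_bf + forearm_sd**2))
    rho = (cov_target - cov_b) / (height_sd * forearm_sd)
    if not -1.0 <= rho <= 1.0:
        warnings.warn(
            f"target height-forearm correlation {target_r} not attainable with "
            f"the configured within-score spreads; clipping", stacklevel=3
        )
        rho = float(np.clip(rho, -0.999, 0.999))
    return rho


def assign_tool_length(height: float) -> float:
    """Tool length (cm) from participant height per the published sizing rule."""
    if height <= 122.0:
        return 25.0
    if height < 147.0:
        return 32.0
    return 40.0


def generate_cohort(
    n_subjects: int,
    puberty_weights: Mapping[int, float] | None = None,
    seed: int | None = None,
    height_sd: float = 7.0,
    forearm_sd: float = 1.8,
    height_forearm_r: float = 0.89,
    age_sd: float = 1.2,
    left_handed_fraction: float = 6 / 90,
) -> list[Subject]:
    """Draw a cohort of subjects with puberty-dependent covariates.

    Puberty scores are drawn from ``puberty_weights`` (default: the published
    per-score sample counts).  When the weights are integer counts summing
    exactly to ``n_subjects`` the composition is reproduced exactly rather
    than sampled.  Height and forearm length are drawn around the published
    per-score means with Gaussian jitter, with the within-score correlation
    solved so the cohort-level height-forearm Pearson correlation matches
    ``height_forearm_r`` in expectation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if puberty_weights is None:
        puberty_weights = dict(PUBERTY_SCORE_COUNTS)
    weights = {int(k): float(v) for k, v in puberty_weights.items()}
    if any(v < 0 for v in weights.values()):
        raise ValueError("puberty weights must be nonnegative")
    if sum(weights.values()) <= 0:
        raise ValueError("puberty weights must not all be zero")
    if any(not PUBERTY_MIN <= k <= PUBERTY_MAX for k in weights):
        raise ValueError("puberty scores must lie in [5, 20]")

    rng = np.random.default_rng(seed)
    scores_avail = sorted(k for k, v in weights.items() if v > 0)

    exact = (
        all(float(v).is_integer() for v in weights.values())
        and int(sum(weights.values())) == n_subjects
    )
    if exact:
        scores = np.repeat(scores_avail, [int(weights[s]) for s in scores_avail])
    else:
        p = np.array([weights[s] for s in scores_avail], dtype=float)
        scores = rng.choice(scores_avail, size=n_subjects, p=p / p.sum())
        scores = np.sort(scores)

    rho = _within_score_correlation(weights, height_sd, forearm_sd, height_forearm_r)

    subjects = []
    for i, ps in enumerate(scores):
        row = COHORT_TABLE.loc[int(ps)]
        z1, z2 = rng.standard_normal(2)
        height = row["height_mean"] + height_sd * z1
        forearm = row["forearm_mean"] + forearm_sd * (
            rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * z2
        )
        forearm = max(forearm, 5.0)
        n_f, n_m = row["n_female"], row["n_male"]
        sex = "F" if rng.random() < n_f / (n_f + n_m) else "M"
        age = max(7.0, row["age_mean"] + age_sd * rng.standard_normal())
        handedness = "L" if rng.random() < left_handed_fraction else "R"
        subjects.append(
            Subject(
                subject_id=f"S{i + 1:03d}",
                puberty_score=int(ps),
                sex=sex,
                age=float(age),
                height=float(height),
                forearm_length=float(forearm),
                handedness=handedness,
                tool_length=assign_tool_length(height),
            )
        )
    return subjects


def cohort_frame(cohort: Sequence[Subject]) -> pd.DataFrame:
    """Cohort as a tidy DataFrame, one row per subject."""
    return pd.DataFrame([dataclasses.asdict(s) for s in cohort])


# ---------------------------------------------------------------------------
# Trial-level parameter generation
# ---------------------------------------------------------------------------

def default_effect_specs(target_crossing: float | None = 16.0) -> dict[str, EffectSpec]:
    """Study-condition effect specifications for the nine parameters.

    Baselines follow a natural-speed 35 cm reach (minimum-jerk values for a
    1 s movement; 70 mm grip aperture opening at 60% of the movement).  The
    interaction slopes are signed so early-puberty subjects show larger
    amplitudes / shorter latencies after tool use and late-puberty subjects
    the adult-like reverse, with the POST-PRE difference crossing zero at
    ``target_crossing``.  Variance components are documented assumptions
    (the published analysis reports none), sized to give realistic
    trial-to-trial scatter relative to the effects.
    """
    tc = target_crossing
    return {
        "acc_latency": EffectSpec(180.0, 0.0, (0.0,), (0.0, 1.5), 15.0, 25.0, tc),
        "acc_amplitude": EffectSpec(2020.0, 0.0, (0.0,), (0.0, -25.0), 120.0, 200.0, tc),
        "vel_latency": EffectSpec(470.0, 0.0, (0.0,), (0.0, 2.5), 15.0, 25.0, tc),
        "vel_amplitude": EffectSpec(656.0, 0.0, (0.0,), (0.0, -8.0), 40.0, 60.0, tc),
        "dec_latency": EffectSpec(760.0, 0.0, (0.0,), (0.0, 3.0), 20.0, 30.0, tc),
        "dec_amplitude": EffectSpec(2020.0, 0.0, (0.0,), (0.0, -25.0), 120.0, 200.0, tc),
        "mga_latency": EffectSpec(600.0, 0.0, (0.0,), (0.0, 4.0), 20.0, 40.0, tc),
        "mga": EffectSpec(70.0, 0.0, (0.0, 0.3), (0.0, -0.6), 3.0, 5.0, tc),
        "movement_time": EffectSpec(1000.0, 0.0, (0.0,), (0.0, 5.0), 40.0, 70.0, tc),
    }


#: Sign with which each parameter loads on the shared trial-level noise
#: component: latencies and movement time move together, amplitudes oppose.
_SHARED_NOISE_SIGN = {
    "acc_latency": 1.0,
    "vel_latency": 1.0,
    "dec_latency": 1.0,
    "mga_latency": 1.0,
    "movement_time": 1.0,
    "acc_amplitude": -1.0,
    "vel_amplitude": -1.0,
    "dec_amplitude": -1.0,
    "mga": -1.0,
}


def generate_trial_parameters(
    cohort: Sequence[Subject],
    effects: Mapping[str, EffectSpec],
    n_trials: int = 18,
    seed: int | None = None,
    condition_col: str = "session",
    condition_levels: tuple[str, str] = ("PRE", "POST"),
    cross_parameter_corr: float = 0.5,
) -> pd.DataFrame:
    """Simulate trial-level parameter values for every subject x condition.

    Returns a long-format table with columns ``subject_id, puberty, sex,
    forearm_length, <condition_col>, trial, parameter, value``.  Each
    parameter follows its :class:`EffectSpec`; ``cross_parameter_corr`` is the
    fraction of residual variance carried by a trial-level component shared
    across parameters (signed so latencies and amplitudes covary negatively,
    as in slower-vs-faster trials), leaving marginal variances unchanged.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= cross_parameter_corr <= 1.0:
        raise ValueError("cross_parameter_corr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    params = list(effects)
    contrasts = {condition_levels[0]: -0.5, condition_levels[1]: +0.5}

    n_subj = len(cohort)
    n_cond = len(condition_levels)
    shared = math.sqrt(cross_parameter_corr)
    indep = math.sqrt(1.0 - cross_parameter_corr)

    # subject random intercepts, independent across parameters
    b = {
        name: effects[name].subject_sd * rng.standard_normal(n_subj)
        for name in params
    }
    z_trial = rng.standard_normal((n_subj, n_cond, n_trials))

    frames = []
    for k, name in enumerate(params):
        spec = effects[name]
        eps = spec.residual_sd * (
            shared * _SHARED_NOISE_SIGN.get(name, 1.0) * z_trial
            + indep * rng.standard_normal((n_subj, n_cond, n_trials))
        )
        for i, subj in enumerate(cohort):
            for j, level in enumerate(condition_levels):
                s = contrasts[level]
                mu = float(spec.mean(subj.puberty_score, s))
                values = mu + b[name][i] + eps[i, j]
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": subj.subject_id,
                            "puberty": subj.puberty_score,
                            "sex": subj.sex,
                            "forearm_length": subj.forearm_length,
                            condition_col: level,
                            "trial": np.arange(1, n_trials + 1),
                            "parameter": name,
                            "value": values,
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    return out


def pivot_trials(long_df: pd.DataFrame, condition_col: str = "session") -> pd.DataFrame:
    """Long trial table -> wide table with one row per trial and one column
    per kinematic parameter (plus subject covariates)."""
    id_cols = [c for c in ("subject_id", "puberty", "sex", "forearm_length",
                           condition_col, "trial") if c in long_df.columns]
    wide = long_df.pivot_table(
        index=id_cols, columns="parameter", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

def _closure_rate_settle_time(amplitude: float, closure_duration: float,
                              rate_threshold: float) -> float:
    """Time after the aperture peak at which the raised-cosine closure rate
    falls below ``rate_threshold`` for good (0 when it never exceeds it)."""
    peak_rate = math.pi * amplitude / (2.0 * closure_duration)
    if peak_rate <= rate_threshold:
        return 0.0
    q = rate_threshold / peak_rate
    return closure_duration * (1.0 - math.asin(q) / math.pi)


def generate_trajectories(
    rows: pd.DataFrame,
    seed: int | None = None,
    sampling_rate: float = 200.0,
    noise_sd: float = 0.01,
    start_aperture: float = 30.0,
    final_aperture: float = 25.0,
    switch_release: float = 0.10,
    motion_start: float = 0.15,
    onset_speed_threshold: float = 10.0,
    end_wrist_speed_threshold: float = 20.0,
    end_aperture_rate_threshold: float = 5.0,
    condition_col: str = "session",
) -> list[TrialRecording]:
    """Embed trial parameters into synthetic 200 Hz marker recordings.

    Each row must carry ``vel_amplitude`` (mm/s), ``movement_time`` (ms),
    ``mga`` (mm) and ``mga_latency`` (ms).  The wrist follows a minimum-jerk
    path whose distance and duration realise the row's peak speed and
    movement time; the thumb-index distance follows a raised-cosine profile
    peaking at the row's MGA at its latency.  Acceleration/deceleration
    parameters are therefore the minimum-jerk-implied values, reported in the
    ``ground_truth`` dict together with the analytic onset (speed-threshold
    crossing) and analytic stabilised-grasp end, i.e. the exact values of the
    estimands the extraction stage measures.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    recordings = []
    for _, row in rows.iterrows():
        if {"acc_latency", "vel_latency", "dec_latency"} <= set(row.index):
            if not (row["acc_latency"] <= row["vel_latency"] <= row["dec_latency"]):
                raise ValueError(
                    f"inconsistent latency ordering in row for subject "
                    f"{row.get('subject_id', '?')}: acc {row['acc_latency']}, "
                    f"vel {row['vel_latency']}, dec {row['dec_latency']}"
                )
        T = float(row["movement_time"]) / 1000.0
        V = float(row["vel_amplitude"])
        mga = float(row["mga"])
        if T <= 0 or V <= 0 or mga <= final_aperture:
            raise ValueError("movement_time, vel_amplitude must be positive and "
                             "mga must exceed the final aperture")
        D = V * T / minjerk.PEAK_SPEED_FACTOR

        tau_on = minjerk.speed_threshold_tau(D, T, onset_speed_threshold)
        t_on = motion_start + tau_on * T
        t_mga = t_on + float(row["mga_latency"]) / 1000.0
        # keep the aperture peak strictly inside the movement; noisy latencies
        # are clamped and the clamped value becomes the embedded ground truth
        t_mga = float(np.clip(t_mga, motion_start + 0.15 * T, motion_start + 0.70 * T))
        mga_latency_embedded = (t_mga - t_on) * 1e3

        tau_slow = minjerk.speed_threshold_tau(D, T, end_wrist_speed_threshold,
                                               rising=False)
        t_speed_settle = motion_start + tau_slow * T
        # grip closure completes at 85% of the movement, i.e. before the
        # wrist decelerates through its end threshold, so the stabilised
        # grasp is governed by the (robust) wrist-speed criterion
        t_close = motion_start + 0.85 * T
        closure = t_close - t_mga
        t_rate_settle = t_mga + _closure_rate_settle_time(
            mga - final_aperture, closure, end_aperture_rate_threshold
        )
        t_end = max(t_speed_settle, t_rate_settle)

        times = np.arange(0.0, motion_start + T + 0.30 + dt / 2, dt)
        tau = (times - motion_start) / T
        y = D * minjerk.position(np.clip(tau, 0.0, 1.0))
        wrist = np.column_stack([np.zeros_like(y), y, np.zeros_like(y)])

        aperture = np.full_like(times, start_aperture)
        opening = (times >= motion_start) & (times < t_mga)
        u = (times[opening] - motion_start) / (t_mga - motion_start)
        aperture[opening] = start_aperture + (mga - start_aperture) * 0.5 * (
            1 - np.cos(np.pi * u)
        )
        closing = (times >= t_mga) & (times < t_close)
        u = (times[closing] - t_mga) / closure
        aperture[closing] = final_aperture + (mga - final_aperture) * 0.5 * (
            1 + np.cos(np.pi * u)
        )
        aperture[times >= t_close] = final_aperture

        offset = np.array([0.0, 60.0, 0.0])  # fingers ahead of the wrist marker
        half = np.column_stack([aperture / 2, np.zeros_like(y), np.zeros_like(y)])
        thumb = wrist + offset + half
        index = wrist + offset - half
        if noise_sd > 0:
            wrist = wrist + rng.normal(0.0, noise_sd, wrist.shape)
            thumb = thumb + rng.normal(0.0, noise_sd, thumb.shape)
            index = index + rng.normal(0.0, noise_sd, index.shape)

        ground_truth = {
            "acc_latency": (motion_start + minjerk.TAU_ACC_PEAK * T - t_on) * 1e3,
            "acc_amplitude": minjerk.PEAK_ACC_FACTOR * D / T**2,
            "vel_latency": (motion_start + minjerk.TAU_VEL_PEAK * T - t_on) * 1e3,
            "vel_amplitude": V,
            "dec_latency": (motion_start + minjerk.TAU_DEC_PEAK * T - t_on) * 1e3,
            "dec_amplitude": minjerk.PEAK_ACC_FACTOR * D / T**2,
            "mga_latency": mga_latency_embedded,
            "mga": mga,
            "movement_time": (t_end - t_on) * 1e3,
        }
        meta_cols = ("puberty", "sex", "forearm_length")
        recordings.append(
            TrialRecording(
                subject_id=str(row.get("subject_id", "S000")),
                condition=str(row.get(condition_col, "PRE")),
                trial_index=int(row.get("trial", 0)),
                times=times,
                wrist=wrist,
                thumb=thumb,
                index=index,
                switch_release_time=switch_release,
                sampling_rate=sampling_rate,
                ground_truth=ground_truth,
                meta={k: row[k] for k in meta_cols if k in row.index},
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# Arm-length estimation and imitation-score generation
# ---------------------------------------------------------------------------

def default_armlength_effect(target_crossing: float | None = 7.5) -> EffectSpec:
    """Arm-length estimation effect on the percent-of-veridical scale:
    POST estimates shrink for subjects above the crossing puberty score."""
    return EffectSpec(
        baseline=100.0,
        session_main=0.0,
        puberty_curve=(0.0,),
        interaction_curve=(0.0, -0.8),
        subject_sd=6.0,
        residual_sd=8.0,
        target_crossing=target_crossing,
    )


def generate_armlength_trials(
    cohort: Sequence[Subject],
    effect: EffectSpec | None = None,
    n_trials: int = 18,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the blindfolded arm-length estimation task.

    The generative model acts on the percent-of-veridical-forearm scale, and
    raw estimated distances (cm) are derived per subject, so the analysis-side
    transform ``100 * estimate / forearm_length`` recovers the generated
    percent values exactly.
    """
    if effect is None:
        effect = default_armlength_effect()
    rng = np.random.default_rng(seed)
    b = effect.subject_sd * rng.standard_normal(len(cohort))
    rows = []
    for i, subj in enumerate(cohort):
        for level, s in (("PRE", -0.5), ("POST", +0.5)):
            pct = (
                float(effect.mean(subj.puberty_score, s))
                + b[i]
                + effect.residual_sd * rng.standard_normal(n_trials)
            )
            for t in range(n_trials):
                rows.append(
                    (
                        subj.subject_id,
                        subj.puberty_score,
                        level,
                        t + 1,
                        pct[t] / 100.0 * subj.forearm_length,
                        subj.forearm_length,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "puberty", "session", "trial", "estimate",
                 "forearm_length"],
    )


def generate_imitation_scores(
    cohort: Sequence[Subject],
    intercept: float = 45.0,
    slope: float = 0.85,
    quadratic: float = 0.0,
    sd: float = 5.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-subject gesture-imitation totals (0-72), linear in puberty by
    default (the published pattern), clipped to the score range."""
    rng = np.random.default_rng(seed)
    rows = []
    for subj in cohort:
        p = subj.puberty_score
        score = intercept + slope * p + quadratic * p * p + sd * rng.standard_normal()
        rows.append((subj.subject_id, p, float(np.clip(score, 0.0, 72.0))))
    return pd.DataFrame(rows, columns=["subject_id", "puberty", "score"])


# ---------------------------------------------------------------------------
# Trial recording I/O (CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def write_recording(recording: TrialRecording, out_dir: str | Path) -> Path:
    """Write one trial as ``<stem>.csv`` (t + marker coordinates) plus a
    ``<stem>.json`` sidecar (switch release, rate, ground truth, metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{recording.subject_id}_{recording.condition}_{recording.trial_index:03d}"
    df = pd.DataFrame({"t": recording.times})
    for name in ("wrist", "thumb", "index"):
        arr = getattr(recording, name)
        for k, axis in enumerate("xyz"):
            df[f"{name}_{axis}"] = arr[:, k]
    csv_path = out_dir / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "subject_id": recording.subject_id,
        "condition": recording.condition,
        "trial_index": recording.trial_index,
        "switch_release_time": recording.switch_release_time,
        "sampling_rate": recording.sampling_rate,
        "ground_truth": recording.ground_truth,
        "meta": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                 for k, v in recording.meta.items()},
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_recording(csv_path: str | Path,
                   column_map: Mapping[str, str] | None = None) -> TrialRecording:
    """Read a trial CSV (+ JSON sidecar if present) back into a recording.

    ``column_map`` renames arbitrary CSV headers onto the canonical
    ``t, wrist_x ... index_z`` schema, the adaptation point for external
    exports.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["t"] + [f"{m}_{a}" for m in ("wrist", "thumb", "index") for a in "xyz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path.name}: missing columns {missing}")
    sidecar_path = csv_path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    times = df["t"].to_numpy(float)
    rate = sidecar.get("sampling_rate") or 1.0 / np.median(np.diff(times))
    return TrialRecording(
        subject_id=str(sidecar.get("subject_id", csv_path.stem)),
        condition=str(sidecar.get("condition", "PRE")),
        trial_index=int(sidecar.get("trial_index", 0)),
        times=times,
        wrist=df[["wrist_x", "wrist_y", "wrist_z"]].to_numpy(float),
        thumb=df[["thumb_x", "thumb_y", "thumb_z"]].to_numpy(float),
        index=df[["index_x", "index_y", "index_z"]].to_numpy(float),
        switch_release_time=float(sidecar.get("switch_release_time", times[0])),
        sampling_rate=float(rate),
        ground_truth=sidecar.get("ground_truth"),
        meta=sidecar.get("meta", {}),
    )
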