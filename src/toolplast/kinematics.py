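"""Extraction of reach-to-grasp kinematic parameters from marker trajectories.

The reaching component is characterised by the latencies and amplitudes of
the wrist acceleration, velocity and deceleration peaks; the grasping
component by the maximum grip aperture (MGA, peak Euclidean thumb-index
distance) and its latency.  Movement time runs from movement onset (wrist
speed >= 10 mm/s after switch release) to stabilised grasp on the object.
Latencies are reported relative to the detected onset, in milliseconds.

Raw positions are low-pass filtered with a zero-phase Butterworth filter
before differencing (zero-phase so peak latencies carry no filter lag); all
thresholds and the filter itself are configurable and bypassable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .simulate import TrialRecording, read_recording

__all__ = [
    "FilterConfig",
    "DetectionConfig",
    "KinematicProfile",
    "TrialParameters",
    "differentiate_and_smooth",
    "detect_onset",
    "detect_grasp_end",
    "extract_trial_parameters",
    "extract_table",
    "mirror_lateral",
]


@dataclass(frozen=True)
class FilterConfig:
    """Zero-phase low-pass filter applied to marker positions.

    The 10 Hz cutoff (4th order) is standard for reach kinematics sampled at
    200 Hz; set ``enabled=False`` to difference the raw positions.
    """

    cutoff_hz: float = 10.0
    order: int = 4
    enabled: bool = True


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for movement-onset and stabilised-grasp detection (all
    configurable; the grasp-end rule is an operational definition)."""

    onset_speed_threshold: float = 10.0      # mm/s
    end_aperture_rate_threshold: float = 5.0  # mm/s, sustained
    end_dwell: float = 0.050                  # s the aperture must stay stable
    end_wrist_speed_threshold: float = 20.0   # mm/s


@dataclass
class KinematicProfile:
    """Derived time series for one trial: tangential wrist speed and
    acceleration (derivative of speed) and grip aperture, all in mm-based
    units on the recording's time base.

    ``aperture`` is computed from the filtered marker positions and feeds the
    rate-based grasp-end detection; ``aperture_raw`` keeps the unfiltered
    thumb-index distance, on which the maximum grip aperture is measured
    (no differentiation is involved there, so filtering would only smear the
    asymmetric opening/closing peak).
    """

    times: np.ndarray
    speed: np.ndarray
    acceleration: np.ndarray
    aperture: np.ndarray
    aperture_raw: np.ndarray | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class TrialParameters:
    """The nine trial-level parameters (latencies in ms from onset)."""

    acc_latency: float
    acc_amplitude: float
    vel_latency: float
    vel_amplitude: float
    dec_latency: float
    dec_amplitude: float
    mga_latency: float
    mga: float
    movement_time: float

    def as_dict(self) -> dict[str, float]:
        return {
            "acc_latency": self.acc_latency,
            "acc_amplitude": self.acc_amplitude,
            "vel_latency": self.vel_latency,
            "vel_amplitude": self.vel_amplitude,
            "dec_latency": self.dec_latency,
            "dec_amplitude": self.dec_amplitude,
            "mga_latency": self.mga_latency,
            "mga": self.mga,
            "movement_time": self.movement_time,
        }


def mirror_lateral(recording: TrialRecording) -> TrialRecording:
    """Mirror the lateral (x) axis, for left-handed subjects recorded with
    mirrored object placement.  Tangential quantities are invariant; the
    helper exists for position-level analyses."""
    flip = np.array([-1.0, 1.0, 1.0])
    return TrialRecording(
        subject_id=recording.subject_id,
        condition=recording.condition,
        trial_index=recording.trial_index,
        times=recording.times,
        wrist=recording.wrist * flip,
        thumb=recording.thumb * flip,
        index=recording.index * flip,
        switch_release_time=recording.switch_release_time,
        sampling_rate=recording.sampling_rate,
        ground_truth=recording.ground_truth,
        meta=recording.meta,
    )


def _lowpass(x: np.ndarray, fs: float, config: FilterConfig) -> np.ndarray:
    if not config.enabled:
        return x
    nyq = fs / 2.0
    if config.cutoff_hz >= nyq:
        raise ValueError(f"cutoff {config.cutoff_hz} Hz at/above Nyquist {nyq} Hz")
    b, a = butter(config.order, config.cutoff_hz / nyq)
    padlen = min(3 * max(len(a), len(b)), x.shape[0] - 2)
    return filtfilt(b, a, x, axis=0, padlen=padlen)


def differentiate_and_smooth(
    recording: TrialRecording, filter_config: FilterConfig | None = None
) -> KinematicProfile:
    """Filter marker positions and derive speed, acceleration and aperture.

    Speed is the norm of the differentiated (smoothed) wrist position,
    acceleration the derivative of speed, and aperture the Euclidean
    thumb-index distance.  Rejects non-uniform sampling and NaN samples.
    """
    config = filter_config or FilterConfig()
    t = np.asarray(recording.times, dtype=float)
    if len(t) < 10:
        raise ValueError("recording too short (< 10 samples)")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform sampling")
    markers = np.dstack([recording.wrist, recording.thumb, recording.index])
    if np.isnan(markers).any():
        bad = np.unique(np.argwhere(np.isnan(markers))[:, 0])
        raise ValueError(f"NaN samples at indices {bad.tolist()[:20]}")

    wrist = _lowpass(recording.wrist, recording.sampling_rate, config)
    thumb = _lowpass(recording.thumb, recording.sampling_rate, config)
    index = _lowpass(recording.index, recording.sampling_rate, config)

    vel = np.gradient(wrist, t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, t)
    aperture = np.linalg.norm(thumb - index, axis=1)
    aperture_raw = np.linalg.norm(recording.thumb - recording.index, axis=1)
    return KinematicProfile(times=t, speed=speed, acceleration=accel,
                            aperture=aperture, aperture_raw=aperture_raw)


def detect_onset(
    profile: KinematicProfile,
    switch_release_time: float,
    threshold: float = 10.0,
) -> float:
    """First sample time at/after switch release where speed >= threshold."""
    if not profile.times[0] <= switch_release_time <= profile.times[-1]:
        raise ValueError("switch_release_time outside the recorded span")
    eligible = (profile.times >= switch_release_time) & (profile.speed >= threshold)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise RuntimeError("no movement detected")
    return float(profile.times[idx[0]])


def detect_grasp_end(
    profile: KinematicProfile,
    onset_time: float,
    config: DetectionConfig | None = None,
) -> float:
    """Time of stabilised grasp: first sample after the grip-closure phase
    where the aperture rate stays below threshold for the dwell window and
    the wrist has slowed below its threshold."""
    config = config or DetectionConfig()
    t = profile.times
    dwell_n = max(1, int(round(config.end_dwell / profile.dt)))
    after_onset = np.flatnonzero(t >= onset_time)
    if after_onset.size == 0:
        raise RuntimeError("no grasp end detected")
    i_mga = after_onset[np.argmax(profile.aperture[after_onset])]
    rate = np.abs(np.gradient(profile.aperture, t))
    for i in range(i_mga + 1, len(t) - dwell_n + 1):
        if profile.speed[i] >= config.end_wrist_speed_threshold:
            continue
        if np.all(rate[i:i + dwell_n] < config.end_aperture_rate_threshold):
            return float(t[i])
    raise RuntimeError("no grasp end detected")


def _refined_peak(t: np.ndarray, y: np.ndarray, i: int,
                  half_window: int = 5) -> tuple[float, float]:
    """Sub-sample peak refinement: least-squares quadratic vertex over a
    short window around the sampled argmax.

    The windowed fit averages measurement noise, which matters for shallow
    extrema (e.g. the acceleration peak of a bell-shaped reach).  Falls back
    to the raw sample at array edges or non-concave fits.
    """
    lo, hi = i - half_window, i + half_window + 1
    if lo < 0 or hi > len(y):
        return float(t[i]), float(y[i])
    ts = t[lo:hi] - t[i]
    coef = np.polynomial.polynomial.polyfit(ts, y[lo:hi], 2)
    if coef[2] >= 0:
        return float(t[i]), float(y[i])
    vertex = -coef[1] / (2.0 * coef[2])
    dt = t[1] - t[0]
    if abs(vertex) > half_window * dt:
        return float(t[i]), float(y[i])
    peak = coef[0] + coef[1] * vertex + coef[2] * vertex**2
    return float(t[i] + vertex), float(peak)


def extract_trial_parameters(
    recording: TrialRecording,
    filter_config: FilterConfig | None = None,
    detection: DetectionConfig | None = None,
) -> TrialParameters:
    """Extract the nine parameters from one recording.

    Windows follow the physiological ordering of a single-peaked reach: the
    acceleration peak is searched before the speed peak, the deceleration
    peak after it, and MGA over the whole onset-to-end window.  Peak values
    and latencies are refined by local parabolic interpolation.
    """
    detection = detection or DetectionConfig()
    profile = differentiate_and_smooth(recording, filter_config)
    onset = detect_onset(profile, recording.switch_release_time,
                         detection.onset_speed_threshold)
    end = detect_grasp_end(profile, onset, detection)

    t = profile.times
    window = np.flatnonzero((t >= onset) & (t <= end))
    if window.size < 3:
        raise RuntimeError("movement window too short")

    i_vel = window[np.argmax(profile.speed[window])]
    t_vel, vel_amp = _refined_peak(t, profile.speed, i_vel)

    # the acceleration extrema are shallow; a wider least-squares window
    # averages the (band-limited) differentiation noise
    acc_window = window[window <= i_vel]
    i_acc = acc_window[np.argmax(profile.acceleration[acc_window])]
    t_acc, acc_amp = _refined_peak(t, profile.acceleration, i_acc, half_window=15)

    dec_window = window[window >= i_vel]
    i_dec = dec_window[np.argmax(-profile.acceleration[dec_window])]
    t_dec, dec_amp = _refined_peak(t, -profile.acceleration, i_dec, half_window=15)

    aperture = (profile.aperture_raw if profile.aperture_raw is not None
                else profile.aperture)
    i_mga = window[np.argmax(aperture[window])]
    t_mga, mga = _refined_peak(t, aperture, i_mga, half_window=2)

    return TrialParameters(
        acc_latency=(t_acc - onset) * 1e3,
        acc_amplitude=acc_amp,
        vel_latency=(t_vel - onset) * 1e3,
        vel_amplitude=vel_amp,
        dec_latency=(t_dec - onset) * 1e3,
        dec_amplitude=dec_amp,
        mga_latency=(t_mga - onset) * 1e3,
        mga=mga,
        movement_time=(end - onset) * 1e3,
    )


def extract_table(
    recordings: Iterable[TrialRecording],
    filter_config: FilterConfig | None = None,
    detection: DetectionConfig | None = None,
    condition_col: str = "session",
) -> pd.DataFrame:
    """Extract parameters from many recordings into the long-format trial
    table consumed by the statistical stages."""
    rows = []
    for rec in recordings:
        params = extract_trial_parameters(rec, filter_config, detection)
        base = {
            "subject_id": rec.subject_id,
            condition_col: rec.condition,
            "trial": rec.trial_index,
        }
        base.update(rec.meta)
        for name, value in params.as_dict().items():
            rows.append({**base, "parameter": name, "value": value})
    return pd.DataFrame(rows)


def load_trial_directory(
    directory: str | Path,
    column_map: dict[str, str] | None = None,
) -> list[TrialRecording]:
    """Read every trial CSV (with optional JSON sidecar) in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trial CSVs found in {directory}")
    return [read_recording(p, column_map) for p in paths]
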