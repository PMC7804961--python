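"""Closed-form minimum-jerk trajectory kernel.

A point-to-point minimum-jerk movement of distance ``D`` and duration ``T``
follows, in normalised time ``tau = t / T`` in [0, 1],

    x(tau) = D (10 tau^3 - 15 tau^4 + 6 tau^5)
    v(tau) = (D / T) 30 tau^2 (1 - tau)^2
    a(tau) = (D / T^2) (60 tau - 180 tau^2 + 120 tau^3)

The speed profile is a symmetric single-peaked bell with

* peak speed 1.875 D / T at tau = 1/2,
* acceleration extrema of magnitude (10 / sqrt(3)) D / T^2 at
  tau = (3 -+ sqrt(3)) / 6.

These closed forms are used both to synthesise wrist trajectories and as the
analytic oracle for the kinematic extraction stage.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

#: Peak-speed coefficient: v_max = PEAK_SPEED_FACTOR * D / T.
PEAK_SPEED_FACTOR = 1.875

#: Peak-acceleration coefficient: a_max = PEAK_ACC_FACTOR * D / T**2.
PEAK_ACC_FACTOR = 10.0 / np.sqrt(3.0)

#: Normalised times of the acceleration maximum, speed maximum and
#: deceleration maximum.
TAU_ACC_PEAK = (3.0 - np.sqrt(3.0)) / 6.0
TAU_VEL_PEAK = 0.5
TAU_DEC_PEAK = (3.0 + np.sqrt(3.0)) / 6.0


def position(tau):
    """Normalised displacement profile; multiply by D for millimetres."""
    tau = np.asarray(tau)
    out = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return np.clip(out, 0.0, 1.0)


def speed(tau):
    """Normalised speed profile; multiply by D/T for mm/s."""
    tau = np.asarray(tau)
    out = 30.0 * tau**2 * (1.0 - tau) ** 2
    return np.where((tau < 0) | (tau > 1), 0.0, out)


def acceleration(tau):
    """Normalised acceleration profile; multiply by D/T**2 for mm/s^2."""
    tau = np.asarray(tau)
    out = 60.0 * tau - 180.0 * tau**2 + 120.0 * tau**3
    return np.where((tau < 0) | (tau > 1), 0.0, out)


def speed_threshold_tau(distance: float, duration: float, threshold: float,
                        rising: bool = True) -> float:
    """Normalised time at which the speed profile crosses ``threshold``.

    With ``rising=True`` the crossing on the rising flank (tau < 1/2) is
    returned; otherwise the mirror-symmetric falling-flank crossing.  Raises
    ``ValueError`` when the peak speed never reaches the threshold.
    """
    v_norm = threshold * duration / distance  # threshold in units of D/T
    if v_norm <= 0:
        raise ValueError("threshold must be positive")
    if v_norm >= 30.0 / 16.0:
        raise ValueError(
            f"peak speed {PEAK_SPEED_FACTOR * distance / duration:.1f} mm/s "
            f"never reaches threshold {threshold:.1f} mm/s"
        )
    tau = brentq(lambda t: 30.0 * t**2 * (1.0 - t) ** 2 - v_norm, 0.0, 0.5)
    return tau if rising else 1.0 - tau
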