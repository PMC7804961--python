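"""Crossing points and intervals of equivalence on the puberty axis.

From a fitted condition-by-puberty mixed model, the two condition curves are
predicted on a fine puberty grid at the fixed-effect level.  The POST-PRE
difference and its delta-method standard error give a pointwise two-sided
Wald z-test per grid point (no multiplicity correction, matching a pointwise
5% significance level).  The crossing point is the sign-change root of the
difference curve (linear interpolation between grid points); the interval of
equivalence is the maximal contiguous run of non-significant grid points
containing the crossing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lmm import ModelFit

log = logging.getLogger(__name__)

__all__ = [
    "ConditionCurves",
    "CrossingResult",
    "predict_condition_curves",
    "pointwise_difference_test",
    "crossing_and_equivalence",
    "aggregate_crossings",
]


@dataclass
class ConditionCurves:
    """Predicted condition curves and their difference on a covariate grid."""

    grid: np.ndarray
    pre_curve: np.ndarray
    post_curve: np.ndarray
    difference: np.ndarray
    difference_se: np.ndarray
    condition_labels: tuple[str, str]

    def __post_init__(self):
        if not np.all(np.isfinite(self.pre_curve) & np.isfinite(self.post_curve)):
            raise ValueError("curves must be finite on the whole grid")
        if np.any(self.difference_se <= 0):
            raise ValueError("difference_se must be positive")


@dataclass
class CrossingResult:
    """Crossing point and interval of equivalence for one parameter."""

    crossing_point: float | None
    all_crossings: list[float]
    equivalence_interval: tuple[float, float] | None
    pointwise_p: np.ndarray = field(repr=False)
    grid: np.ndarray = field(repr=False)
    alpha: float = 0.05
    no_reversal: bool = False
    min_abs_z_point: float | None = None

    def interval_as_integers(self) -> tuple[int, int] | None:
        """Equivalence interval with endpoints rounded outward to integer
        puberty scores (table-style output); the exact endpoints stay in
        ``equivalence_interval``."""
        if self.equivalence_interval is None:
            return None
        lo, hi = self.equivalence_interval
        g_lo, g_hi = float(self.grid[0]), float(self.grid[-1])
        return (int(max(g_lo, np.floor(lo))), int(min(g_hi, np.ceil(hi))))


def predict_condition_curves(
    fit: ModelFit,
    lo: float = 5.0,
    hi: float = 20.0,
    step: float = 0.01,
) -> ConditionCurves:
    """Predict both condition curves on a covariate grid.

    Predictions are at the fixed-effect level (random effects at zero); the
    difference standard error comes from the delta contrast c' V c with
    c the difference of the two design rows.  Grids extending beyond the
    observed covariate range are flagged as extrapolation.
    """
    grid = np.arange(lo, hi + step / 2, step)
    obs_lo, obs_hi = fit.covariate_range
    if lo < obs_lo - 1e-9 or hi > obs_hi + 1e-9:
        warnings.warn(
            f"grid [{lo}, {hi}] extends beyond observed covariate range "
            f"[{obs_lo}, {obs_hi}]; predictions are extrapolated",
            stacklevel=2,
        )
    labels = sorted(fit.condition_contrasts, key=fit.condition_contrasts.get)
    label_pre, label_post = labels[0], labels[-1]
    rows_pre = fit.design_row(label_pre, grid)
    rows_post = fit.design_row(label_post, grid)
    pre = rows_pre @ fit.params
    post = rows_post @ fit.params
    c = rows_post - rows_pre
    var = np.einsum("ij,jk,ik->i", c, fit.cov_params, c)
    se = np.sqrt(np.maximum(var, 1e-300))
    return ConditionCurves(
        grid=grid,
        pre_curve=pre,
        post_curve=post,
        difference=post - pre,
        difference_se=se,
        condition_labels=(label_pre, label_post),
    )


def pointwise_difference_test(curves: ConditionCurves, alpha: float = 0.05) -> np.ndarray:
    """Two-sided Wald z-test of the condition difference at each grid point."""
    z = curves.difference / curves.difference_se
    return 2.0 * stats.norm.sf(np.abs(z))


def _nonsignificant_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as (start, stop) inclusive indices."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def crossing_and_equivalence(
    curves: ConditionCurves, alpha: float = 0.05
) -> CrossingResult:
    """Locate the crossing point and its interval of equivalence.

    All sign-change roots of the difference are interpolated linearly; when
    several exist, the primary crossing is the one inside the widest
    non-significant run (logged).  With no sign change the result is flagged
    ``no_reversal`` and the interval (if any) is anchored at the
    minimum-|z| grid point, so the procedure degrades gracefully on data
    without an interaction.
    """
    grid = curves.grid
    d = curves.difference
    p = pointwise_difference_test(curves, alpha)

    sign_change = np.flatnonzero(np.sign(d[:-1]) * np.sign(d[1:]) < 0)
    roots = [
        float(grid[i] + (grid[i + 1] - grid[i]) * d[i] / (d[i] - d[i + 1]))
        for i in sign_change
    ]
    exact_zero = np.flatnonzero(d == 0.0)
    roots.extend(float(grid[i]) for i in exact_zero
                 if 0 < i < len(d) - 1 and d[i - 1] * d[i + 1] < 0)
    roots = sorted(set(roots))

    mask = p > alpha
    runs = _nonsignificant_runs(mask)

    def run_containing(value: float):
        for start, stop in runs:
            if grid[start] - 1e-12 <= value <= grid[stop] + 1e-12:
                return (start, stop)
        return None

    crossing = None
    interval_run = None
    if roots:
        if len(roots) > 1:
            log.info("multiple crossings %s; picking the one in the widest "
                     "non-significant run", [round(r, 3) for r in roots])
            best = None
            for r in roots:
                run = run_containing(r)
                width = (run[1] - run[0]) if run else -1
                if best is None or width > best[1]:
                    best = (r, width, run)
            crossing, _, interval_run = best
        else:
            crossing = roots[0]
            interval_run = run_containing(crossing)

    i_min = int(np.argmin(np.abs(d / curves.difference_se)))
    min_z_point = float(grid[i_min])
    no_reversal = crossing is None
    if no_reversal:
        interval_run = run_containing(min_z_point)

    interval = None
    if interval_run is not None:
        interval = (float(grid[interval_run[0]]), float(grid[interval_run[1]]))
        if crossing is not None:
            # tolerance: the root interpolation can sit a few ulp outside
            crossing = float(np.clip(crossing, interval[0], interval[1])) \
                if interval[0] - 1e-9 <= crossing <= interval[1] + 1e-9 else crossing
            assert interval[0] <= crossing <= interval[1], (
                "equivalence interval must contain the crossing point"
            )
    return CrossingResult(
        crossing_point=crossing,
        all_crossings=roots,
        equivalence_interval=interval,
        pointwise_p=p,
        grid=grid,
        alpha=alpha,
        no_reversal=no_reversal,
        min_abs_z_point=min_z_point,
    )


def aggregate_crossings(results, meta_result: CrossingResult | None = None) -> dict:
    """Mean and median of per-parameter crossing points, with the
    meta-parameter crossing (and its global interval of equivalence) as the
    primary estimate when available.

    ``results`` maps parameter names to :class:`CrossingResult` objects or
    plain crossing-point numbers (so published tables can be aggregated
    directly); parameters without a crossing are excluded.
    """
    if not isinstance(results, dict):
        results = {f"param_{i}": r for i, r in enumerate(results)}
    crossings = {}
    for name, r in results.items():
        value = r.crossing_point if isinstance(r, CrossingResult) else r
        if value is not None:
            crossings[name] = float(value)
    summary: dict = {
        "per_parameter": crossings,
        "n_with_crossing": len(crossings),
        "no_reversal_detected": len(crossings) == 0,
    }
    if crossings:
        values = np.array(list(crossings.values()))
        summary["mean"] = float(values.mean())
        summary["median"] = float(np.median(values))
    else:
        summary["mean"] = summary["median"] = None
    if meta_result is not None:
        summary["meta_crossing"] = meta_result.crossing_point
        summary["meta_interval"] = meta_result.equivalence_interval
        summary["meta_interval_int"] = meta_result.interval_as_integers()
        summary["primary"] = "meta-parameter"
    return summary
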