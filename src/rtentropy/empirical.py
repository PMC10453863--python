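"""Empirical survivor functions — the substrate of the plug-in CRE estimator.

With no censoring, the nonparametric estimate of S(t) = Pr{T > t} is the
complement of the ECDF: a right-continuous step function that drops by
(multiplicity / n) at each distinct observed duration, equal to 1 before
the first observation and 0 at and beyond the largest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import isotonic_regression

from .curves import FunctionCurve
from .exceptions import UsageError, ValidationError

__all__ = ["RTSample", "EmpiricalSurvivor", "empirical_survivor", "interpolate_survivor"]


@dataclass(frozen=True)
class RTSample:
    """A finite sample of observed positive durations (ms).

    Durations must be finite and strictly positive; an optional condition
    label identifies the experimental condition the sample came from.
    """

    durations: np.ndarray
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        x = np.asarray(self.durations, dtype=float).ravel()
        object.__setattr__(self, "durations", x)
        if x.size == 0:
            raise UsageError("empty sample")
        bad = np.flatnonzero(~np.isfinite(x) | (x <= 0))
        if bad.size:
            raise ValidationError(
                f"durations must be finite and > 0; first offending row: "
                f"{bad[0]} (value {x[bad[0]]!r})"
            )

    @property
    def n(self) -> int:
        return int(self.durations.size)


@dataclass(frozen=True)
class EmpiricalSurvivor:
    """Right-continuous step estimate of the survivor function.

    ``step_values[k]`` is S(t) for t in [step_times[k], step_times[k+1]);
    S(t) = 1 for t < step_times[0] and 0 at and after the last step time.
    Tied observations collapse into a single step.
    """

    step_times: np.ndarray
    step_values: np.ndarray
    n: int
    condition: Optional[str] = None

    def __call__(self, t) -> np.ndarray:
        """Evaluate S(t) (right-continuous) at arbitrary times."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.step_times, t, side="right")
        vals = np.concatenate([[1.0], self.step_values])
        return vals[idx]

    @property
    def max_observation(self) -> float:
        return float(self.step_times[-1])


def empirical_survivor(sample: RTSample) -> EmpiricalSurvivor:
    """Estimate S(t) = #(T > t)/n from an uncensored sample."""
    times, counts = np.unique(sample.durations, return_counts=True)
    n = sample.n
    values = 1.0 - np.cumsum(counts) / n
    values[-1] = 0.0  # exact, not subject to float cancellation
    return EmpiricalSurvivor(times, values, n, sample.condition)


def _corner_points(curve: EmpiricalSurvivor):
    # the (t, S) knots an interpolant must pass through, anchored at (0, 1)
    if curve.step_times[0] > 0:
        t = np.concatenate([[0.0], curve.step_times])
        s = np.concatenate([[1.0], curve.step_values])
    else:  # pragma: no cover - durations are strictly positive
        t, s = curve.step_times, curve.step_values
    return t, s


def interpolate_survivor(curve: EmpiricalSurvivor, grid, method: str = "step") -> FunctionCurve:
    """Tabulate an empirical survivor on a grid.

    ``step`` reproduces the exact right-continuous step function;
    ``linear`` and ``natural_spline`` pass through the post-drop corner
    points (anchored at S(0)=1).  A natural cubic spline can overshoot
    and wiggle between knots, so its values are clipped to [0, 1] and then
    projected onto the nonincreasing cone by isotonic regression (pool
    adjacent violators), which repairs local violations without letting a
    single dip clamp the whole tail; the number of repaired points is
    recorded under ``meta['monotonicity_repairs']``.
    """
    grid = np.asarray(grid, dtype=float)
    meta = {"n": curve.n, "interpolation": method}
    if curve.condition is not None:
        meta["condition"] = curve.condition
    if method == "step":
        vals = curve(grid)
        return FunctionCurve(grid, vals, "survivor", meta)
    tk, sk = _corner_points(curve)
    if method == "linear":
        vals = np.interp(grid, tk, sk, left=1.0, right=0.0)
        return FunctionCurve(grid, vals, "survivor", meta)
    if method == "natural_spline":
        if tk.size < 2:
            raise UsageError("natural_spline needs at least two knots")
        spline = CubicSpline(tk, sk, bc_type="natural")
        vals = np.where(grid <= tk[0], 1.0,
                        np.where(grid >= tk[-1], 0.0, spline(grid)))
        clipped = np.clip(vals, 0.0, 1.0)
        repaired = np.clip(isotonic_regression(clipped, increasing=False).x, 0.0, 1.0)
        meta["monotonicity_repairs"] = int(np.count_nonzero(repaired != vals))
        return FunctionCurve(grid, repaired, "survivor", meta)
    raise UsageError(f"unknown interpolation method {method!r}; "
                     "use step, linear or natural_spline")
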