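"""Cumulative residual entropy (CRE) and instantaneous CRE for durations.

The CRE of a nonnegative random variable with survivor function S is

    CRE = -integral S(t) * log S(t) dt,

a differential entropy defined on the survivor function rather than the
density.  Unlike the density-based differential entropy it is always
nonnegative, vanishes only for a point mass, and the plug-in estimate on
the empirical survivor converges to the true value.  It is shift
invariant, scales linearly (CRE(aX) = a CRE(X)) and carries units of
time x information: for an exponential of rate lam it equals the mean,
1/lam (in nats).

Pointwise quantities derived from it:

* the CRE density  eps'(t) = -S(t) log S(t), the integrand above;
* the instantaneous CRE  iCRE(t) = -log S(t), the unweighted momentary
  information gained from the stimulus by time t — numerically identical
  to the integrated hazard H(t);
* the slope of iCRE(t) against t, the rate of information gain
  (for an exponential it is exactly the rate lam).

Estimators: exact closed forms where they exist, trapezoidal quadrature
on tabulated survivor curves, and plug-in estimates on the empirical
survivor (exact piecewise-constant sum for the step form).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

import numpy as np
import statsmodels.api as sm

from .curves import S_FLOOR, FunctionCurve
from .distributions import Exponential
from .empirical import RTSample, empirical_survivor, interpolate_survivor
from .exceptions import EstimatorError, UsageError, ValidationError
from .units import NATS, LogBase

__all__ = [
    "EntropyResult", "ICRECurve", "SlopeFit",
    "cre_from_survivor", "cre_exponential_analytic", "cre_empirical",
    "cre_density", "icre", "icre_from_sample", "icre_slope",
    "hazard_in_bits", "discrete_entropy",
]

#: default lower-quantile cut for the iCRE slope fit: keep the latest 10%
#: of curve points, where the iCRE of a right-skewed duration model has
#: entered its linear (exponential-tail) regime
DEFAULT_FIT_LOWER_QUANTILE = 0.9


@dataclass(frozen=True)
class EntropyResult:
    """A CRE value with its unit, integration bounds and estimation method."""

    value: float
    base: LogBase
    lower: float
    upper: float
    method: str
    n: Optional[int] = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise UsageError(f"bounds must satisfy lower < upper, got "
                             f"({self.lower}, {self.upper})")

    @property
    def units(self) -> str:
        return f"{self.base.unit} x ms"


@dataclass(frozen=True)
class ICRECurve:
    """iCRE(t) = -log S(t): nonnegative, nondecreasing information vs time."""

    t: np.ndarray
    values: np.ndarray
    base: LogBase
    excluded_tail: int = 0
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape or t.size == 0:
            raise ValidationError("t and values must be nonempty 1-d arrays of equal length")
        if np.any(v < -1e-12):
            raise ValidationError("iCRE values must be nonnegative")

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("t,icre\n")
            for ti, vi in zip(self.t, self.values):
                fh.write(f"{float(ti)!r},{float(vi)!r}\n")


@dataclass(frozen=True)
class SlopeFit:
    """An OLS fit of iCRE(t) against t: the information-gain rate."""

    slope: float
    intercept: float
    stderr: float
    fit_window: Tuple[float, float]
    n_points: int
    rss: float
    base: LogBase

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValidationError("slope is not finite")
        if self.n_points < 3:
            raise EstimatorError("slope fit needs at least 3 points")

    @property
    def units(self) -> str:
        return f"{self.base.unit}/ms"


def _integrand(S: np.ndarray, base: LogBase) -> np.ndarray:
    """-S log S with the limit convention 0 at S in {0, 1}."""
    S = np.clip(S, 0.0, 1.0)
    interior = (S > 0.0) & (S < 1.0)
    out = np.zeros_like(S)
    out[interior] = -S[interior] * base.log(S[interior])
    return out


def _check_survivor_values(values: np.ndarray) -> None:
    if np.any(values < -1e-9) or np.any(values > 1 + 1e-9):
        raise ValidationError("survivor values must lie in [0, 1]")


def cre_from_survivor(curve: FunctionCurve, lower: Optional[float] = None,
                      upper: Optional[float] = None,
                      base: LogBase = NATS) -> EntropyResult:
    """CRE by trapezoidal quadrature of -S log S on a tabulated survivor.

    The grid is restricted to [lower, upper]; the integrand is taken as 0
    wherever S is 0 or 1 (its analytic limit).
    """
    if curve.kind != "survivor":
        raise UsageError(f"cre_from_survivor expects a survivor curve, got {curve.kind!r}")
    _check_survivor_values(curve.values)
    lo = curve.t[0] if lower is None else float(lower)
    hi = curve.t[-1] if upper is None else float(upper)
    if not lo < hi:
        raise UsageError(f"bounds must satisfy lower < upper, got ({lo}, {hi})")
    mask = (curve.t >= lo) & (curve.t <= hi)
    if np.count_nonzero(mask) < 2:
        raise UsageError("fewer than 2 grid points inside the integration bounds")
    t = curve.t[mask]
    w = _integrand(curve.values[mask], base)
    value = float(np.trapezoid(w, t))
    return EntropyResult(max(value, 0.0), base, lo, hi, "quadrature",
                         n=curve.meta.get("n"), meta=dict(curve.meta))


def cre_exponential_analytic(model, base: LogBase = NATS) -> EntropyResult:
    """Closed-form CRE of an exponential: its mean 1/lam (in nats).

    ``model`` may be an :class:`~rtentropy.distributions.Exponential` or a
    bare positive rate.
    """
    if not isinstance(model, Exponential):
        model = Exponential(float(model))
    value = (1.0 / model.lam) * base.log(math.e)
    return EntropyResult(float(value), base, 0.0, math.inf, "analytic",
                         meta={"lam": model.lam})


def cre_empirical(sample: RTSample, method: str = "step", base: LogBase = NATS,
                  upper: Optional[float] = None,
                  grid_points: int = 10_000) -> EntropyResult:
    """Plug-in CRE on the empirical survivor of an observed sample.

    For ``method='step'`` the integral has the exact piecewise-constant
    closed form  sum_k (-S_k log S_k) (t_{k+1} - t_k);  for ``linear`` and
    ``natural_spline`` the interpolated survivor is integrated by
    trapezoidal quadrature on a uniform grid of ``grid_points`` intervals.
    The empirical survivor is 0 beyond the largest observation, so any
    ``upper`` past it adds nothing.
    """
    if sample.n < 2:
        raise EstimatorError("the plug-in CRE estimator needs at least 2 observations")
    es = empirical_survivor(sample)
    hi = es.max_observation if upper is None else float(upper)
    if hi < es.max_observation:
        hi_eff = hi
    else:
        hi_eff = es.max_observation
    meta = {"interpolation": method}
    if sample.condition is not None:
        meta["condition"] = sample.condition
    if method == "step":
        # segment [times_k, times_{k+1}) carries constant S
        times = np.concatenate([[0.0], es.step_times])
        svals = np.concatenate([[1.0], es.step_values])
        times = np.minimum(times, hi_eff)
        widths = np.diff(times)
        value = float(np.sum(_integrand(svals[:-1], base) * widths))
        return EntropyResult(max(value, 0.0), base, 0.0, hi, "empirical_step",
                             n=sample.n, meta=meta)
    grid = np.linspace(0.0, hi_eff, int(grid_points) + 1)
    curve = interpolate_survivor(es, grid, method=method)
    res = cre_from_survivor(curve, base=base)
    return EntropyResult(res.value, base, 0.0, hi, f"empirical_{method}",
                         n=sample.n, meta=meta)


def cre_density(survivor_curve: FunctionCurve, base: LogBase = NATS) -> FunctionCurve:
    """The CRE density eps'(t) = -S(t) log S(t), the integrand of the CRE.

    Nonnegative, 0 wherever S is 0 or 1, with global maximum 1/e (nats)
    attained where S = 1/e.
    """
    if survivor_curve.kind != "survivor":
        raise UsageError(f"cre_density expects a survivor curve, got {survivor_curve.kind!r}")
    _check_survivor_values(survivor_curve.values)
    meta = dict(survivor_curve.meta)
    meta["base"] = base.unit
    return FunctionCurve(survivor_curve.t, _integrand(survivor_curve.values, base),
                         "cre_density", meta)


def icre(survivor_curve: FunctionCurve, base: LogBase = NATS,
         s_floor: float = S_FLOOR) -> ICRECurve:
    """iCRE(t) = -log S(t), the information gained from the stimulus by t.

    Identical in value to the integrated hazard H(t).  Grid points with
    S(t) below ``s_floor`` (where iCRE diverges) are dropped and counted
    in ``excluded_tail``.
    """
    if survivor_curve.kind != "survivor":
        raise UsageError(f"icre expects a survivor curve, got {survivor_curve.kind!r}")
    _check_survivor_values(survivor_curve.values)
    S = np.clip(survivor_curve.values, 0.0, 1.0)
    keep = S >= s_floor
    if not np.any(keep):
        raise ValidationError("survivor is 0 everywhere on the grid")
    vals = -base.log(S[keep])
    return ICRECurve(survivor_curve.t[keep], np.maximum(vals, 0.0), base,
                     excluded_tail=int(np.count_nonzero(~keep)),
                     meta=dict(survivor_curve.meta))


def icre_from_sample(sample: RTSample, base: LogBase = NATS) -> ICRECurve:
    """Empirical iCRE evaluated at the sorted observations.

    S is the empirical survivor, so at the k-th order statistic (ties
    collapsed) iCRE = -log((n - cum_count_k)/n); the largest observation,
    where S = 0, is excluded.
    """
    es = empirical_survivor(sample)
    keep = es.step_values > 0
    vals = -base.log(es.step_values[keep])
    meta = {"n": sample.n}
    if sample.condition is not None:
        meta["condition"] = sample.condition
    return ICRECurve(es.step_times[keep], vals, base,
                     excluded_tail=int(np.count_nonzero(~keep)), meta=meta)


def icre_slope(curve: ICRECurve,
               fit_lower_quantile: float = DEFAULT_FIT_LOWER_QUANTILE,
               trim_upper_quantile: float = 0.0,
               weights=None) -> SlopeFit:
    """Information-gain rate: OLS slope of iCRE(t) against t.

    The fit window keeps the last ``1 - fit_lower_quantile`` fraction of
    the curve's points (after dropping the ``trim_upper_quantile`` tail
    fraction).  The default window — the upper decile — targets the
    asymptotic regime where the iCRE of right-skewed duration models is
    linear with slope equal to the tail rate (1/tau for the ex-Gaussian,
    lam for the exponential); the early curved onset would otherwise bias
    the rate downward.  Set ``fit_lower_quantile=0`` for a full-window fit.
    For an exactly linear curve any window returns the same slope.
    """
    if not 0.0 <= fit_lower_quantile < 1.0:
        raise UsageError(f"fit_lower_quantile must be in [0, 1), got {fit_lower_quantile}")
    if not 0.0 <= trim_upper_quantile < 1.0:
        raise UsageError(f"trim_upper_quantile must be in [0, 1), got {trim_upper_quantile}")
    m = len(curve)
    hi = m - int(math.floor(trim_upper_quantile * m))
    lo = int(math.floor(fit_lower_quantile * m))
    t, y = curve.t[lo:hi], curve.values[lo:hi]
    if weights is not None:
        weights = np.asarray(weights, dtype=float)[lo:hi]
    if t.size < 3:
        raise EstimatorError(
            f"slope fit needs at least 3 points in the window, got {t.size}")
    X = sm.add_constant(t)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    fit = model.fit()
    return SlopeFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                    stderr=float(fit.bse[1]), fit_window=(float(t[0]), float(t[-1])),
                    n_points=int(t.size), rss=float(fit.ssr), base=curve.base)


def hazard_in_bits(hazard_curve: FunctionCurve) -> FunctionCurve:
    """Rescale a hazard to information rate in bits: h(t) / ln 2."""
    if hazard_curve.kind != "hazard":
        raise UsageError(f"hazard_in_bits expects a hazard curve, got {hazard_curve.kind!r}")
    meta = dict(hazard_curve.meta)
    meta["units"] = "bits per time unit"
    return FunctionCurve(hazard_curve.t, hazard_curve.values / math.log(2.0),
                         "hazard", meta)


def discrete_entropy(p, base: LogBase = NATS) -> float:
    """Shannon entropy -sum p log p of a discrete distribution (0 log 0 = 0)."""
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < 0) or np.any(~np.isfinite(p)):
        raise ValidationError("probabilities must be finite and nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities must sum to 1, got {p.sum()!r}")
    nz = p > 0
    return float(-np.sum(p[nz] * base.log(p[nz])))
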