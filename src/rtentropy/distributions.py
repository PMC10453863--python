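"""Parametric response-time models: ex-Gaussian and exponential.

The ex-Gaussian — the convolution of a Gaussian N(mu, sigma^2) with an
exponential of mean tau — is the workhorse parametric model for response
times: unimodal, right-skewed, with mean mu + tau and variance
sigma^2 + tau^2.  The exponential (rate lam, mean 1/lam) is the canonical
memoryless duration model with a constant hazard lam.

Each model exposes the five canonical duration-analysis functions as
tabulated :class:`~rtentropy.curves.FunctionCurve` objects on an explicit
time grid (density, CDF, survivor, hazard, cumulative hazard), plus exact
moments and seeded random sampling.  Evaluation is delegated to
scipy.stats (``exponnorm`` implements the numerically stable exp-log form
of the ex-Gaussian's Gaussian-CDF closed form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import curves as _curves
from .curves import FunctionCurve
from .empirical import RTSample
from .exceptions import ParameterError, UsageError
from .units import NATS, LogBase

__all__ = ["ExGaussian", "Exponential", "DEFAULT_EXGAUSS_GRID", "DEFAULT_EXP_GRID"]

#: default tabulation grid for ex-Gaussian curves: [0, 2500] ms, 1 ms step
DEFAULT_EXGAUSS_GRID = (0.0, 2500.0, 1.0)
#: default tabulation grid for exponential curves: [0, 30], 0.01 step
DEFAULT_EXP_GRID = (0.0, 30.0, 0.01)


def make_grid(lower: float, upper: float, step: float) -> np.ndarray:
    """Closed grid from ``lower`` to ``upper`` inclusive with spacing ``step``."""
    if not (np.isfinite(lower) and np.isfinite(upper) and lower < upper and step > 0):
        raise UsageError(f"invalid grid ({lower}, {upper}, {step})")
    n = int(round((upper - lower) / step))
    return lower + step * np.arange(n + 1)


class _ParametricModel:
    """Shared curve plumbing; subclasses provide ``_frozen`` and ``_meta``."""

    def _grid(self, t) -> np.ndarray:
        if t is None:
            t = make_grid(*self.default_grid)
        return np.asarray(t, dtype=float)

    def pdf(self, t=None) -> FunctionCurve:
        t = self._grid(t)
        return FunctionCurve(t, self._frozen.pdf(t), "pdf", self._meta())

    def cdf(self, t=None) -> FunctionCurve:
        t = self._grid(t)
        return FunctionCurve(t, self._frozen.cdf(t), "cdf", self._meta())

    def survivor(self, t=None) -> FunctionCurve:
        t = self._grid(t)
        return FunctionCurve(t, self._frozen.sf(t), "survivor", self._meta())

    def hazard(self, t=None) -> FunctionCurve:
        t = self._grid(t)
        return _curves.hazard(self.pdf(t), self.survivor(t))

    def cumulative_hazard(self, t=None, base: LogBase = NATS) -> FunctionCurve:
        return _curves.cumulative_hazard(self.survivor(t), base=base)

    def rvs(self, n: int, seed) -> RTSample:
        if n < 1:
            raise UsageError(f"sample size must be >= 1, got {n}")
        if seed is None:
            raise UsageError("a seed must be set explicitly for sampling")
        return self._sample(int(n), np.random.default_rng(seed))


@dataclass(frozen=True)
class ExGaussian(_ParametricModel):
    """Ex-Gaussian duration model with parameters (mu, sigma, tau) in ms."""

    mu: float
    sigma: float
    tau: float

    default_grid = DEFAULT_EXGAUSS_GRID

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ParameterError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if not (self.tau > 0 and np.isfinite(self.tau)):
            raise ParameterError(f"tau must be > 0, got {self.tau}")

    @property
    def _frozen(self):
        return stats.exponnorm(K=self.tau / self.sigma, loc=self.mu, scale=self.sigma)

    @property
    def mean(self) -> float:
        return self.mu + self.tau

    @property
    def var(self) -> float:
        return self.sigma ** 2 + self.tau ** 2

    def _meta(self) -> dict:
        return {"model": "exgauss", "mu": self.mu, "sigma": self.sigma,
                "tau": self.tau,
                "label": f"exgauss(mu={self.mu:g},sigma={self.sigma:g},tau={self.tau:g})"}

    def _sample(self, n: int, rng: np.random.Generator) -> RTSample:
        x = rng.normal(self.mu, self.sigma, n) + rng.exponential(self.tau, n)
        # durations are positive by definition; redraw the (vanishingly rare
        # at plausible RT parameters) Gaussian excursions below zero
        bad = x <= 0
        while np.any(bad):
            k = int(np.count_nonzero(bad))
            x[bad] = rng.normal(self.mu, self.sigma, k) + rng.exponential(self.tau, k)
            bad = x <= 0
        return RTSample(x)


@dataclass(frozen=True)
class Exponential(_ParametricModel):
    """Exponential duration model with rate ``lam`` (mean 1/lam)."""

    lam: float

    default_grid = DEFAULT_EXP_GRID

    def __post_init__(self) -> None:
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ParameterError(f"lam must be > 0, got {self.lam}")

    @property
    def _frozen(self):
        return stats.expon(scale=1.0 / self.lam)

    @property
    def mean(self) -> float:
        return 1.0 / self.lam

    @property
    def var(self) -> float:
        return 1.0 / self.lam ** 2

    def _meta(self) -> dict:
        return {"model": "exponential", "lam": self.lam,
                "label": f"exponential(lam={self.lam:g})"}

    def pdf(self, t=None) -> FunctionCurve:
        # scipy's expon.pdf already returns 0 for t < 0; spelled out for clarity
        t = self._grid(t)
        vals = np.where(t < 0, 0.0, self.lam * np.exp(-self.lam * np.maximum(t, 0.0)))
        return FunctionCurve(t, vals, "pdf", self._meta())

    def _sample(self, n: int, rng: np.random.Generator) -> RTSample:
        return RTSample(rng.exponential(1.0 / self.lam, n))
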