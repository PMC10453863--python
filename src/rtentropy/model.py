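"""Model/Results interface for entropy analysis of one duration sample.

:class:`RTEntropy` is built from observed durations; ``fit()`` estimates
the total cumulative residual entropy (plug-in on the empirical survivor)
and the information-gain rate (OLS slope of the empirical iCRE curve) and
returns an :class:`RTEntropyResults` carrying the estimates, the slope's
standard error, the fitted curves and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import entropy as ent
from .empirical import RTSample, empirical_survivor
from .exceptions import UsageError
from .units import NATS, LogBase

__all__ = ["RTEntropy", "RTEntropyResults"]


class RTEntropy:
    """Nonparametric entropy model for a sample of response times.

    Parameters
    ----------
    durations : array-like of positive times (ms), or an :class:`RTSample`.
    condition : optional label for the experimental condition.
    base : information unit (default nats).
    upper : upper integration limit for the CRE (default: the largest
        observation; the empirical survivor is 0 beyond it).
    interpolation : survivor interpolation for the CRE integral
        (``step`` uses the exact piecewise-constant sum).
    fit_lower_quantile, trim_upper_quantile : iCRE slope fit window; see
        :func:`rtentropy.entropy.icre_slope`.
    """

    def __init__(self, durations, condition: Optional[str] = None,
                 base: LogBase = NATS, upper: Optional[float] = None,
                 interpolation: str = "step",
                 fit_lower_quantile: float = ent.DEFAULT_FIT_LOWER_QUANTILE,
                 trim_upper_quantile: float = 0.0):
        if isinstance(durations, RTSample):
            self.sample = durations if condition is None else RTSample(
                durations.durations, condition)
        else:
            self.sample = RTSample(durations, condition)
        self.base = base
        self.upper = upper
        self.interpolation = interpolation
        self.fit_lower_quantile = fit_lower_quantile
        self.trim_upper_quantile = trim_upper_quantile

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, rt: str = "rt",
                       condition: Optional[str] = None, **kwargs):
        """Build one model per condition from a tidy dataframe.

        Returns a single model if ``condition`` is None, otherwise a dict
        mapping condition label to model.
        """
        if rt not in data.columns:
            raise UsageError(f"column {rt!r} not found in dataframe")
        if condition is None:
            return cls(data[rt].to_numpy(), **kwargs)
        if condition not in data.columns:
            raise UsageError(f"column {condition!r} not found in dataframe")
        return {str(label): cls(grp[rt].to_numpy(), condition=str(label), **kwargs)
                for label, grp in data.groupby(condition, sort=True)}

    def fit(self) -> "RTEntropyResults":
        cre = ent.cre_empirical(self.sample, method=self.interpolation,
                                base=self.base, upper=self.upper)
        icre_curve = ent.icre_from_sample(self.sample, base=self.base)
        slope = ent.icre_slope(icre_curve,
                               fit_lower_quantile=self.fit_lower_quantile,
                               trim_upper_quantile=self.trim_upper_quantile)
        return RTEntropyResults(self, cre, icre_curve, slope)


class RTEntropyResults:
    """Estimates from :meth:`RTEntropy.fit`.

    Attributes
    ----------
    cre : :class:`~rtentropy.entropy.EntropyResult`, total CRE.
    icre : :class:`~rtentropy.entropy.ICRECurve`, empirical iCRE(t).
    slope : :class:`~rtentropy.entropy.SlopeFit`, information-gain rate.
    params : pandas Series with ``cre``, ``icre_slope``, ``icre_intercept``.
    """

    def __init__(self, model: RTEntropy, cre, icre_curve, slope):
        self.model = model
        self.cre = cre
        self.icre = icre_curve
        self.slope = slope
        self.params = pd.Series({"cre": cre.value, "icre_slope": slope.slope,
                                 "icre_intercept": slope.intercept})

    @property
    def nobs(self) -> int:
        return self.model.sample.n

    def summary(self) -> str:
        m = self.model
        unit = m.base.unit
        cond = m.sample.condition or "-"
        lines = [
            "          RT entropy analysis",
            "=" * 46,
            f"condition:        {cond}",
            f"n observations:   {self.nobs}",
            f"log base / unit:  {m.base.base:g} ({unit})",
            f"CRE method:       {self.cre.method}",
            f"integration:      [{self.cre.lower:g}, {self.cre.upper:g}] ms",
            "-" * 46,
            f"CRE               {self.cre.value:12.4f}  {unit} x ms",
            f"iCRE slope        {self.slope.slope:12.6f}  {unit}/ms",
            f"  std err         {self.slope.stderr:12.6f}",
            f"  intercept       {self.slope.intercept:12.4f}  {unit}",
            f"  fit window      [{self.slope.fit_window[0]:.1f}, "
            f"{self.slope.fit_window[1]:.1f}] ms ({self.slope.n_points} points)",
            f"  residual SS     {self.slope.rss:12.4f}",
            f"excluded S=0 pts  {self.icre.excluded_tail:6d}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready summary of the analysis."""
        m = self.model
        return {
            "condition": m.sample.condition,
            "n": self.nobs,
            "base": m.base.unit,
            "method": self.cre.method,
            "lower": self.cre.lower,
            "upper": self.cre.upper,
            "cre": self.cre.value,
            "icre_slope": self.slope.slope,
            "icre_slope_stderr": self.slope.stderr,
            "fit_window": list(self.slope.fit_window),
            "n_fit_points": self.slope.n_points,
            "excluded_tail": self.icre.excluded_tail,
        }

    def plot_icre(self, ax=None, show_fit: bool = True):
        """Plot the empirical iCRE curve and, optionally, the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = self.model.sample.condition
        ax.plot(self.icre.t, self.icre.values, lw=1.0, label=label)
        if show_fit:
            lo, hi = self.slope.fit_window
            tt = np.array([lo, hi])
            ax.plot(tt, self.slope.intercept + self.slope.slope * tt, "--", lw=1.0)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel(f"iCRE(t) ({self.model.base.unit})")
        if label:
            ax.legend()
        return ax

    def plot_survivor(self, ax=None):
        """Plot the empirical survivor step function."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        es = empirical_survivor(self.model.sample)
        t = np.concatenate([[0.0], es.step_times])
        s = np.concatenate([[1.0], es.step_values])
        ax.step(t, s, where="post", lw=1.0, label=self.model.sample.condition)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("S(t)")
        return ax
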