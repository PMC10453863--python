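"""Tabulated duration-distribution curves and the identities linking them.

A :class:`FunctionCurve` is a function of time tabulated on an explicit,
strictly increasing grid, tagged with what it represents: a density f(t),
a CDF F(t), a survivor function S(t) = 1 - F(t), a hazard h(t) = f(t)/S(t),
or a cumulative (integrated) hazard H(t) = -log S(t).  The transforms in
this module enforce those identities rather than recomputing from a model,
so they apply equally to theoretical and empirical curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import UsageError, ValidationError
from .units import NATS, LogBase

__all__ = ["FunctionCurve", "survivor_from_cdf", "hazard", "cumulative_hazard"]

#: points with S(t) below this floor are dropped from hazard / -log S
#: computations to avoid division/log blow-ups
S_FLOOR = 1e-12

_KINDS = ("pdf", "cdf", "survivor", "hazard", "cumulative_hazard", "cre_density")
_MONO_TOL = 1e-9


@dataclass(frozen=True)
class FunctionCurve:
    """A kind-tagged function of time on a strictly increasing grid.

    Parameters
    ----------
    t : array of times (ms), strictly increasing and finite.
    values : function values at each grid point.
    kind : one of ``pdf``, ``cdf``, ``survivor``, ``hazard``,
        ``cumulative_hazard``, ``cre_density``.
    meta : free-form provenance (parameters, excluded points, units).
    """

    t: np.ndarray
    values: np.ndarray
    kind: str
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if self.kind not in _KINDS:
            raise UsageError(f"unknown curve kind {self.kind!r}")
        if t.ndim != 1 or v.shape != t.shape:
            raise ValidationError("t and values must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValidationError("empty grid")
        if not np.all(np.isfinite(t)):
            raise ValidationError("grid contains non-finite times")
        if not np.all(np.diff(t) > 0):
            raise ValidationError("grid must be strictly increasing")
        self._check_values(v)

    def _check_values(self, v: np.ndarray) -> None:
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{self.kind} curve contains non-finite values")
        if self.kind in ("pdf", "hazard", "cumulative_hazard", "cre_density"):
            if np.any(v < -_MONO_TOL):
                raise ValidationError(f"{self.kind} values must be nonnegative")
        if self.kind in ("cdf", "survivor"):
            if np.any(v < -_MONO_TOL) or np.any(v > 1 + _MONO_TOL):
                raise ValidationError(f"{self.kind} values must lie in [0, 1]")
        diffs = np.diff(v)
        if self.kind in ("cdf", "cumulative_hazard") and np.any(diffs < -_MONO_TOL):
            raise ValidationError(f"{self.kind} values must be nondecreasing")
        if self.kind == "survivor" and np.any(diffs > _MONO_TOL):
            raise ValidationError("survivor values must be nonincreasing")

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path) -> None:
        """Write as two columns ``t,value`` with a header naming the curve."""
        label = self.meta.get("label", self.kind)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"t,{label}\n")
            for ti, vi in zip(self.t, self.values):
                fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def _require_kind(curve: FunctionCurve, kind: str, what: str) -> None:
    if curve.kind != kind:
        raise UsageError(f"{what} expects a {kind} curve, got {curve.kind!r}")


def survivor_from_cdf(cdf_curve: FunctionCurve) -> FunctionCurve:
    """S(t) = 1 - F(t), elementwise on the CDF's grid."""
    _require_kind(cdf_curve, "cdf", "survivor_from_cdf")
    return FunctionCurve(cdf_curve.t, 1.0 - cdf_curve.values, "survivor",
                         dict(cdf_curve.meta))


def hazard(pdf_curve: FunctionCurve, survivor_curve: FunctionCurve,
           s_floor: float = S_FLOOR) -> FunctionCurve:
    """h(t) = f(t) / S(t) on the shared grid.

    Points where S(t) < ``s_floor`` are dropped; their count is recorded
    under ``meta['excluded_tail']``.
    """
    _require_kind(pdf_curve, "pdf", "hazard")
    _require_kind(survivor_curve, "survivor", "hazard")
    if not np.array_equal(pdf_curve.t, survivor_curve.t):
        raise UsageError("hazard requires pdf and survivor on the same grid")
    keep = survivor_curve.values >= s_floor
    if not np.any(keep):
        raise ValidationError("survivor is below the floor everywhere")
    meta = dict(survivor_curve.meta)
    meta["excluded_tail"] = int(np.count_nonzero(~keep))
    h = pdf_curve.values[keep] / survivor_curve.values[keep]
    return FunctionCurve(pdf_curve.t[keep], np.maximum(h, 0.0), "hazard", meta)


def cumulative_hazard(survivor_curve: FunctionCurve, base: LogBase = NATS,
                      s_floor: float = S_FLOOR) -> FunctionCurve:
    """H(t) = -log S(t) in the configured base.

    Identical in value to the instantaneous cumulative residual entropy
    iCRE(t); see :mod:`rtentropy.entropy`.  Points with S(t) < ``s_floor``
    are excluded and counted in ``meta['excluded_tail']``.
    """
    _require_kind(survivor_curve, "survivor", "cumulative_hazard")
    keep = survivor_curve.values >= s_floor
    if not np.any(keep):
        raise ValidationError("survivor is below the floor everywhere")
    meta = dict(survivor_curve.meta)
    meta["excluded_tail"] = int(np.count_nonzero(~keep))
    meta["base"] = base.unit
    vals = -base.log(np.clip(survivor_curve.values[keep], s_floor, 1.0))
    return FunctionCurve(survivor_curve.t[keep], np.maximum(vals, 0.0),
                         "cumulative_hazard", meta)
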