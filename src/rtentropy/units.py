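"""Information units: bits (log base 2), nats (base e) and bans (base 10).

Entropies measured in different bases differ only by a constant factor,
``log_b(a)``; :func:`convert_units` applies it exactly.  One ban is
``log2(10) ~ 3.3219`` bits, one nat is ``1/ln 2 ~ 1.4427`` bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import UsageError

__all__ = ["LogBase", "BITS", "NATS", "BANS", "convert_units"]

_UNIT_NAMES = {2.0: "bits", math.e: "nats", 10.0: "bans"}


@dataclass(frozen=True)
class LogBase:
    """A logarithm base together with the name of its information unit."""

    base: float

    def __post_init__(self) -> None:
        if not (self.base > 0 and self.base != 1 and math.isfinite(self.base)):
            raise UsageError(f"invalid logarithm base: {self.base!r}")

    @property
    def unit(self) -> str:
        return _UNIT_NAMES.get(self.base, f"log{self.base:g}-units")

    def log(self, x):
        """Logarithm of ``x`` in this base (elementwise for arrays)."""
        return np.log(x) / math.log(self.base)

    @classmethod
    def from_name(cls, name: str) -> "LogBase":
        key = str(name).strip().lower()
        table = {
            "bits": 2.0, "2": 2.0,
            "nats": math.e, "e": math.e, "nat": math.e,
            "bans": 10.0, "10": 10.0, "ban": 10.0, "bit": 2.0,
        }
        if key not in table:
            raise UsageError(f"unknown log base {name!r}; use one of 2/e/10 or bits/nats/bans")
        return cls(table[key])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LogBase({self.unit})"


BITS = LogBase(2.0)
NATS = LogBase(math.e)
BANS = LogBase(10.0)


def convert_units(value: float, from_base: LogBase, to_base: LogBase) -> float:
    """Convert an information quantity between log bases.

    Multiplies by ``log_to(from)``; the round trip is the identity.
    """
    if isinstance(from_base, (int, float)):
        from_base = LogBase(float(from_base))
    if isinstance(to_base, (int, float)):
        to_base = LogBase(float(to_base))
    return value * math.log(from_base.base) / math.log(to_base.base)
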