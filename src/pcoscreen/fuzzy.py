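"""Triangular fuzzy numbers and the arithmetic used throughout the screener.

A triangular fuzzy number (TFN) ``(l, m, u)`` represents an imprecise
quantity whose membership rises linearly from 0 at ``l`` to 1 at the mode
``m`` and falls back to 0 at ``u``.  Every linguistic scale in the package
(AHP judgment intensities, criterion-relevance labels, alternative ratings)
resolves to a TFN, and the decision methods reduce to a handful of
component-wise operations on these triples plus a defuzzification and a
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable


@dataclass(frozen=True, slots=True)
class TFN:
    """Triangular fuzzy number with support ``[l, u]`` and mode ``m``.

    Invariant ``l <= m <= u`` is enforced on construction.
    """

    l: float
    m: float
    u: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.l) and math.isfinite(self.m) and math.isfinite(self.u)):
            raise ValueError(f"TFN components must be finite, got {(self.l, self.m, self.u)}")
        if not (self.l <= self.m <= self.u):
            raise ValueError(f"TFN requires l <= m <= u, got {(self.l, self.m, self.u)}")

    @classmethod
    def crisp(cls, v: float) -> "TFN":
        """Promote a crisp scalar to the degenerate TFN ``(v, v, v)``."""
        return cls(v, v, v)

    def __add__(self, other: "TFN") -> "TFN":
        return TFN(self.l + other.l, self.m + other.m, self.u + other.u)

    def __mul__(self, other: "TFN") -> "TFN":
        # Component-wise product; exact only for non-negative operands,
        # which is all the scales this package ships.
        if self.l < 0 or other.l < 0:
            raise ValueError("TFN multiplication is defined here for non-negative operands only")
        return TFN(self.l * other.l, self.m * other.m, self.u * other.u)

    def reciprocal(self) -> "TFN":
        """Fuzzy reciprocal ``(1/u, 1/m, 1/l)``.

        Rejects supports touching zero: a zero lower bound marks a
        degenerate scale entry whose reciprocal is unbounded.
        """
        if self.l <= 0:
            raise ValueError(f"reciprocal requires a strictly positive support, got l={self.l}")
        return TFN(1.0 / self.u, 1.0 / self.m, 1.0 / self.l)

    def scale(self, factor: float) -> "TFN":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return TFN(self.l * factor, self.m * factor, self.u * factor)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.l, self.m, self.u)


def coa_defuzzify(a: TFN) -> float:
    """Center-of-area defuzzification, ``(l + m + u) / 3``."""
    return (a.l + a.m + a.u) / 3.0


def vertex_distance(a: TFN, b: TFN) -> float:
    """Vertex distance between two TFNs.

    Root-mean-square of the three component differences:
    ``sqrt(((l1-l2)^2 + (m1-m2)^2 + (u1-u2)^2) / 3)``.  Symmetric,
    non-negative, zero iff the operands are equal, and satisfies the
    triangle inequality (it is a Euclidean metric up to a constant).
    """
    return math.sqrt(((a.l - b.l) ** 2 + (a.m - b.m) ** 2 + (a.u - b.u) ** 2) / 3.0)


def tfn_sum(values: Iterable[TFN]) -> TFN:
    """Component-wise sum of a non-empty iterable of TFNs."""
    it = iter(values)
    try:
        total = next(it)
    except StopIteration:
        raise ValueError("tfn_sum requires at least one value") from None
    for v in it:
        total = total + v
    return total
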