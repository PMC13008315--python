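"""Typed one-sided bounds for censored assay quantities.

A permeability too fast to quantify is reported only as exceeding a cutoff
(e.g. "> 500e-6 cm/s").  Such values are carried through all downstream
arithmetic as :class:`Bound` objects so they never silently degrade to point
estimates; dividing by a lower bound yields an upper bound and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

BoundKind = Literal["exact", "lower", "upper"]


@dataclass(frozen=True)
class Bound:
    """A number that may be known only as a one-sided bound.

    ``kind == "exact"`` is an ordinary value; ``"lower"`` means the true
    quantity exceeds ``value`` ("> value"); ``"upper"`` means it is below
    ``value`` ("< value").
    """

    value: float
    kind: BoundKind = "exact"

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "lower", "upper"):
            raise ValueError(f"invalid bound kind: {self.kind!r}")

    @property
    def is_exact(self) -> bool:
        return self.kind == "exact"

    @property
    def is_censored(self) -> bool:
        return self.kind != "exact"

    def reciprocal_kind(self) -> BoundKind:
        """Bound kind of 1/x (and of c/x for c > 0)."""
        return {"exact": "exact", "lower": "upper", "upper": "lower"}[self.kind]

    def scaled(self, factor: float) -> "Bound":
        """Multiply by a positive constant, preserving the bound direction."""
        if factor < 0:
            raise ValueError("scaling a bound by a negative factor is undefined")
        return Bound(self.value * factor, self.kind)

    def __format__(self, spec: str) -> str:
        prefix = {"exact": "", "lower": "> ", "upper": "< "}[self.kind]
        return prefix + format(self.value, spec)

    def __str__(self) -> str:
        return self.__format__("g")


def divide(numerator: Bound, denominator: Bound) -> Bound:
    """Bound-propagating division ``numerator / denominator``.

    Supports an exact numerator over an exact or one-sided denominator, and a
    one-sided numerator over an exact denominator.  Both sides censored is
    indeterminate and rejected.
    """
    if numerator.is_censored and denominator.is_censored:
        raise ValueError("ratio of two censored values is indeterminate")
    if denominator.value == 0 and denominator.kind != "lower":
        raise ZeroDivisionError("division by an exact or upper-bounded zero")
    q = numerator.value / denominator.value
    if denominator.is_censored:
        return Bound(q, denominator.reciprocal_kind())
    return Bound(q, numerator.kind)


def parse_bound(text: str) -> Bound:
    """Parse ``"3.1"``, ``"> 500"`` or ``"<0.24"`` into a :class:`Bound`."""
    s = text.strip()
    if s.startswith(">"):
        return Bound(float(s[1:]), "lower")
    if s.startswith("<"):
        return Bound(float(s[1:]), "upper")
    return Bound(float(s))
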