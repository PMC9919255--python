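"""Exact-rational probability plumbing shared across the package.

Every probability derived from the four-genotype sample space is a rational
number with denominator ``4**m``.  Carrying them as :class:`fractions.Fraction`
keeps table reproduction and oracle arbitration free of floating-point noise;
floats appear only at the display edge, through an explicit half-up rounding
policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational

__all__ = ["ExactProbability", "round_half_up", "format_fixed"]


def _as_fraction(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, float):
        # floats are exact binary rationals; callers wanting decimal intent
        # should pass a string or Fraction
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot interpret {x!r} as an exact rational")


def round_half_up(x, decimals: int) -> float:
    """Round ``x`` half-up to ``decimals`` places, exactly, returning a float.

    Python's built-in ``round`` is banker's rounding; printed genetics tables
    conventionally round halves up (0.0625 -> 0.063 at 3 decimals), so the
    rounding is done on the exact rational before any float conversion.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    fr = _as_fraction(x) * 10**decimals
    q, r = divmod(fr.numerator, fr.denominator)
    if 2 * r >= fr.denominator:
        q += 1
    return q / 10**decimals


def format_fixed(x, decimals: int) -> str:
    """Fixed-point decimal string of ``x`` rounded half-up to ``decimals``."""
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    fr = _as_fraction(x) * 10**decimals
    q, r = divmod(fr.numerator, fr.denominator)
    if 2 * r >= fr.denominator:
        q += 1
    sign = "-" if q < 0 else ""
    q = abs(q)
    if decimals == 0:
        return f"{sign}{q}"
    return f"{sign}{q // 10**decimals}.{q % 10**decimals:0{decimals}d}"


@dataclass(frozen=True)
class ExactProbability:
    """A probability carried as an exact rational.

    ``value`` is the exact :class:`~fractions.Fraction`; :attr:`float_view`
    and :meth:`round` give controlled float/display views.
    """

    value: Fraction

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", Fraction(self.value))
        if not 0 <= self.value <= 1:
            raise ValueError(f"probability {self.value} outside [0, 1]")

    @classmethod
    def from_ratio(cls, numerator: int, denominator: int) -> "ExactProbability":
        return cls(Fraction(numerator, denominator))

    @property
    def numerator(self) -> int:
        return self.value.numerator

    @property
    def denominator(self) -> int:
        return self.value.denominator

    @property
    def float_view(self) -> float:
        return float(self.value)

    def round(self, decimals: int) -> float:
        return round_half_up(self.value, decimals)

    def format(self, decimals: int) -> str:
        return format_fixed(self.value, decimals)

    def __float__(self) -> float:
        return float(self.value)

    def __add__(self, other):
        if isinstance(other, ExactProbability):
            return ExactProbability(self.value + other.value)
        if isinstance(other, Rational):
            return ExactProbability(self.value + other)
        return NotImplemented

    __radd__ = __add__

    def __eq__(self, other) -> bool:
        if isinstance(other, ExactProbability):
            return self.value == other.value
        if isinstance(other, Rational):
            return self.value == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.value)
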