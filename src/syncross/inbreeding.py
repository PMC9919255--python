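"""Inbreeding coefficient of a synthetic variety formed from single crosses.

A synthetic variety is produced by random mating of ``m`` sampled plants from
each of ``s`` single crosses whose parent lines have inbreeding coefficient
``F``.  Writing ``m = 4x + e`` (``x`` complete sets of the four GEA genotypes
plus ``e`` leftover plants of distinct genotypes), the expected inbreeding
coefficient of the synthetic is

    F_syn = [ m/2 + (12x + e(e-1)) (1+2F)/6 + (16x(x-1) + 8xe) (1+F)/4 ]
            / (m^2 s)

The three numerator terms are the ``m`` selfings (mean 1/2 each), the
intragroup crosses within each group of four and among the ``e`` extras
(mean (1+2F)/6), and the intergroup crosses between groups and between
groups and extras (mean (1+F)/4).  Only intraparental matings contribute:
the lines of different single crosses are unrelated.

All arithmetic is exact rational; floats appear only in display helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .exact import round_half_up

__all__ = [
    "SyntheticDesign",
    "InbreedingResult",
    "decompose",
    "fsyn",
    "fsyn_limit",
    "fsyn_table",
    "nibd_variance",
]


def decompose(m: int) -> tuple[int, int]:
    """Split a sample size into ``m = 4x + e`` with ``x >= 0``, ``e in 0..3``."""
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")
    return divmod(m, 4)


def _check_design(m: int, F, s: int) -> None:
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")
    if not isinstance(s, int) or s < 1:
        raise ValueError(f"number of parent single crosses s must be >= 1, got {s!r}")
    if not 0 <= F <= 1:
        raise ValueError(f"line inbreeding coefficient F must be in [0, 1], got {F}")


@dataclass(frozen=True)
class SyntheticDesign:
    """The triple (m, F, s) defining a synthetic-variety sampling design.

    m: plants sampled per parent single cross.
    F: inbreeding coefficient of the parent lines, in [0, 1].
    s: number of parent single crosses.
    """

    m: int
    F: Fraction | float
    s: int = 1

    def __post_init__(self) -> None:
        _check_design(self.m, self.F, self.s)

    @property
    def x(self) -> int:
        """Number of complete groups of four in the sample."""
        return self.m // 4

    @property
    def e(self) -> int:
        """Leftover plants beyond the complete groups of four (0..3)."""
        return self.m % 4


@dataclass(frozen=True)
class InbreedingResult:
    """Exact inbreeding coefficient with its numerator decomposition.

    ``selfing``, ``intragroup`` and ``intergroup`` are the three numerator
    contributions *before* division by ``m^2 s``; ``value`` is their sum
    divided by ``m^2 s``, as an exact Fraction.
    """

    design: SyntheticDesign
    selfing: Fraction
    intragroup: Fraction
    intergroup: Fraction
    value: Fraction = field(init=False)

    def __post_init__(self) -> None:
        total = self.selfing + self.intragroup + self.intergroup
        object.__setattr__(
            self, "value", total / (self.design.m**2 * self.design.s)
        )

    @property
    def float_view(self) -> float:
        return float(self.value)

    def round(self, decimals: int) -> float:
        return round_half_up(self.value, decimals)

    def __float__(self) -> float:
        return float(self.value)


def fsyn(design, F=None, s: int = 1) -> InbreedingResult:
    """Exact inbreeding coefficient of the synthetic, F_syn(m, F, s).

    Accepts either a :class:`SyntheticDesign` or scalars ``fsyn(m, F, s)``.
    The result holds the three numerator components (selfings, intragroup
    crosses at (1+2F)/6, intergroup crosses at (1+F)/4) and their exact sum
    divided by ``m^2 s``.
    """
    if not isinstance(design, SyntheticDesign):
        design = SyntheticDesign(design, F, s)
    m, x, e = design.m, design.x, design.e
    Fr = Fraction(design.F)
    selfing = Fraction(m, 2)
    intragroup = (12 * x + e * (e - 1)) * (1 + 2 * Fr) / 6
    intergroup = (16 * x * (x - 1) + 8 * x * e) * (1 + Fr) / 4
    return InbreedingResult(design, selfing, intragroup, intergroup)


def fsyn_limit(F, s: int = 1) -> Fraction:
    """Large-sample plateau (1+F)/(4s): the exact value whenever 4 | m."""
    _check_design(4, F, s)
    return (1 + Fraction(F)) / (4 * s)


def fsyn_table(
    m_values,
    F_values,
    s: int = 1,
    decimals: int = 4,
) -> pd.DataFrame:
    """Grid of F_syn values, rounded half-up to ``decimals``.

    Rows are indexed by ``m``; columns are labelled ``F=<value>``.  With
    ``m_values = 1..24``, ``F_values = (0, 0.5, 0.75, 0.875, 1)``, ``s = 1``
    and ``decimals = 4`` this reproduces the standard 24 x 5 reference grid.
    """
    m_values = list(m_values)
    F_values = list(F_values)
    if not m_values or not F_values:
        raise ValueError("m_values and F_values must be non-empty")
    cols = {}
    for F in F_values:
        label = f"F={format(float(F), 'g')}"
        cols[label] = [fsyn(m, F, s).round(decimals) for m in m_values]
    table = pd.DataFrame(cols, index=pd.Index(m_values, name="m"))
    return table


def nibd_variance(m: int, F):
    """Variance of the number of non-identical-by-descent founder genes.

    For a sample of ``m`` plants from one single cross, the number of
    distinct (non-IBD) founder genes they carry has variance
    ``(2**(m+2) - 8) (1 - F)**2 / 4**m``: zero at ``m = 1`` or ``F = 1``,
    and decreasing in ``F`` for fixed ``m >= 2``.
    """
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")
    if not 0 <= F <= 1:
        raise ValueError(f"F must be in [0, 1], got {F}")
    return (2 ** (m + 2) - 8) * (1 - Fraction(F)) ** 2 / 4**m
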