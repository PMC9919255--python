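"""Probability that a sample contains all four single-cross genotypes.

A sample of size ``m`` drawn with replacement from the genotypic array of a
single cross (four genotypes, each at frequency 1/4) contains all four
genotypes only if the genotype counts form a partition of ``m`` into exactly
four positive parts — a *frequency set*.  Each frequency set with counts
(f1, f2, f3, f4) contributes

    NF * NP / 4**m

to the inclusion probability, where NF = m!/(f1! f2! f3! f4!) counts the
orderings of one assignment of counts to genotypes and NP = 4!/(prod P_l!)
counts the distinct assignments (P_l being the multiplicities of the
distinct count values).  Summing over all frequency sets gives the
enumeration route; the inclusion–exclusion closed form

    1 - 4 (3/4)**m + 6 (2/4)**m - 4 (1/4)**m

is kept alongside as an independent cross-check.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from math import factorial
from numbers import Rational

from .exact import ExactProbability

__all__ = [
    "FrequencySet",
    "enumerate_frequency_sets",
    "nf",
    "np_permutations",
    "per_sf_probability",
    "inclusion_probability",
    "inclusion_probability_closed_form",
    "min_m_for_inclusion",
]


@dataclass(frozen=True)
class FrequencySet:
    """A size-4 multiset of positive genotype counts, canonically sorted.

    ``counts`` sums to the sample size ``m``; ``multiplicity_profile`` gives,
    for each distinct count value in increasing order, how many of the four
    positions carry it (these multiplicities drive NP).
    """

    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 4:
            raise ValueError(f"a frequency set has exactly 4 counts, got {counts}")
        if any(c < 1 for c in counts):
            raise ValueError(f"all genotype counts must be >= 1, got {counts}")
        if tuple(sorted(counts)) != counts:
            raise ValueError(f"counts must be sorted non-decreasing, got {counts}")
        object.__setattr__(self, "counts", counts)

    @property
    def m(self) -> int:
        return sum(self.counts)

    @property
    def multiplicity_profile(self) -> tuple[int, ...]:
        ctr = Counter(self.counts)
        return tuple(ctr[v] for v in sorted(ctr))


def enumerate_frequency_sets(m: int) -> list[FrequencySet]:
    """All partitions of ``m`` into exactly four positive parts, sorted.

    Empty for ``m < 4`` (a sample smaller than four cannot contain all four
    genotypes).
    """
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")
    sets = []
    for a in range(1, m // 4 + 1):
        for b in range(a, (m - a) // 3 + 1):
            for c in range(b, (m - a - b) // 2 + 1):
                d = m - a - b - c
                if d >= c:
                    sets.append(FrequencySet((a, b, c, d)))
    return sets


def nf(m: int, fs: FrequencySet) -> int:
    """Multinomial count of orderings of the frequency set in an m-sample."""
    if fs.m != m:
        raise ValueError(f"frequency set {fs.counts} does not sum to m={m}")
    out = factorial(m)
    for c in fs.counts:
        out //= factorial(c)
    return out


def np_permutations(fs: FrequencySet) -> int:
    """Distinct assignments of the four counts to the four genotypes."""
    out = factorial(4)
    for p in fs.multiplicity_profile:
        out //= factorial(p)
    return out


def per_sf_probability(m: int, fs: FrequencySet) -> ExactProbability:
    """Probability contributed by one frequency set: NF * NP / 4**m."""
    return ExactProbability.from_ratio(nf(m, fs) * np_permutations(fs), 4**m)


def inclusion_probability(m: int) -> ExactProbability:
    """Probability that an m-sample includes all four genotypes (exact).

    Computed by frequency-set enumeration; zero for ``m < 4``.
    """
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")
    total = Fraction(0)
    for fs in enumerate_frequency_sets(m):
        total += per_sf_probability(m, fs).value
    return ExactProbability(total)


def inclusion_probability_closed_form(m: int) -> ExactProbability:
    """Inclusion–exclusion closed form; independent of the enumeration."""
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")
    value = (
        1
        - 4 * Fraction(3, 4) ** m
        + 6 * Fraction(2, 4) ** m
        - 4 * Fraction(1, 4) ** m
    )
    return ExactProbability(value)


def _as_threshold(threshold) -> Fraction:
    # float thresholds are read at decimal face value (0.95 -> 19/20), not as
    # their binary-float neighbours, since the comparison is exact
    if isinstance(threshold, float):
        return Fraction(str(threshold))
    if isinstance(threshold, Rational):
        return Fraction(threshold)
    return Fraction(threshold)


def min_m_for_inclusion(threshold, rounding_decimals: int | None = None) -> int:
    """Smallest ``m`` whose inclusion probability reaches ``threshold``.

    With ``rounding_decimals`` set, each probability is rounded half-up to
    that many places before the comparison — the convention under which the
    traditional answer for a 0.95 threshold is m = 15 (the exact value at
    m = 15 is 0.94673..., first exceeding 0.95 at m = 16).
    """
    thr = _as_threshold(threshold)
    if not 0 < thr < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    for m in itertools.count(4):
        p = inclusion_probability(m).value
        if rounding_decimals is not None:
            shifted = p * 10**rounding_decimals
            q, r = divmod(shifted.numerator, shifted.denominator)
            if 2 * r >= shifted.denominator:
                q += 1
            p = Fraction(q, 10**rounding_decimals)
        if p >= thr:
            return m
    raise AssertionError("unreachable: inclusion probability tends to 1")
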