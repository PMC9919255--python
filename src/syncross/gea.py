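"""Genotypic array of a single cross and its coancestry kernel.

A single cross between two unrelated inbred lines A1A2 and B1B2 produces
exactly four genotypes — A1B1, A1B2, A2B1, A2B2 — each at frequency 1/4
(the genotypic array, GEA).  Random mating among plants carrying these
genotypes generates progeny whose inbreeding coefficient depends only on how
many gene labels the two parents share and on the inbreeding coefficient
``F`` of the parent lines (the probability that a line's two genes are
identical by descent):

* two shared labels (selfing, or two plants of the same genotype) -> 1/2,
* one shared label -> (1 + F)/4,
* no shared label (A1B1 x A2B2 or A1B2 x A2B1) -> F/2.

These three values are the whole 4 x 4 mating kernel; everything downstream
(the synthetic-variety inbreeding coefficient, the gene-dropping simulator)
is built on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational

__all__ = [
    "GeneLabel",
    "Genotype",
    "GEA_GENOTYPES",
    "A1B1",
    "A1B2",
    "A2B1",
    "A2B2",
    "coancestry",
    "kernel_means",
]


@dataclass(frozen=True)
class GeneLabel:
    """One of a line's two genes at the locus.

    ``line`` is "A" or "B"; ``index`` is 1 or 2.  The two lines of a single
    cross are unrelated, so labels from different lines are never identical
    by descent; whether A1 is identical by descent to A2 is governed by the
    line inbreeding coefficient ``F`` elsewhere.
    """

    line: str
    index: int

    def __post_init__(self) -> None:
        if self.line not in ("A", "B"):
            raise ValueError(f"line must be 'A' or 'B', got {self.line!r}")
        if self.index not in (1, 2):
            raise ValueError(f"gene index must be 1 or 2, got {self.index!r}")

    @property
    def founder_id(self) -> str:
        """Globally unique symbol used for identity-by-descent bookkeeping."""
        return f"{self.line}{self.index}"

    def __str__(self) -> str:
        return self.founder_id


@dataclass(frozen=True)
class Genotype:
    """A single-cross plant's genotype: one gene from each parent line."""

    gene_a: GeneLabel
    gene_b: GeneLabel

    def __post_init__(self) -> None:
        if self.gene_a.line != "A" or self.gene_b.line != "B":
            raise ValueError(
                "a single-cross genotype carries one gene from line A and one "
                f"from line B, got {self.gene_a}, {self.gene_b}"
            )

    @property
    def labels(self) -> frozenset[GeneLabel]:
        return frozenset((self.gene_a, self.gene_b))

    @property
    def name(self) -> str:
        return f"{self.gene_a}{self.gene_b}"

    def __str__(self) -> str:
        return self.name


A1B1 = Genotype(GeneLabel("A", 1), GeneLabel("B", 1))
A1B2 = Genotype(GeneLabel("A", 1), GeneLabel("B", 2))
A2B1 = Genotype(GeneLabel("A", 2), GeneLabel("B", 1))
A2B2 = Genotype(GeneLabel("A", 2), GeneLabel("B", 2))

#: The genotypic array of a single cross: each genotype at frequency 1/4.
GEA_GENOTYPES: tuple[Genotype, ...] = (A1B1, A1B2, A2B1, A2B2)


def _check_f(F) -> None:
    if not 0 <= F <= 1:
        raise ValueError(f"line inbreeding coefficient F must be in [0, 1], got {F}")


def _consts(F):
    """(1/2, 1/4, exactness-matched) — Fractions iff F is rational."""
    if isinstance(F, Rational):
        return Fraction(1, 2), Fraction(1, 4)
    return 0.5, 0.25


def coancestry(g1: Genotype, g2: Genotype, F):
    """Inbreeding coefficient of the progeny of the mating ``g1`` x ``g2``.

    Exact (Fraction in, Fraction out) when ``F`` is rational.  Symmetric in
    its genotype arguments; depends only on the number of shared gene labels.
    """
    _check_f(F)
    half, quarter = _consts(F)
    shared = len(g1.labels & g2.labels)
    if shared == 2:
        return half
    if shared == 1:
        return (1 + F) * quarter
    return F * half


def kernel_means(F):
    """Marginal means of the 4 x 4 coancestry kernel.

    Returns ``(selfing_mean, intragroup_cross_mean, grand_mean)`` =
    ``(1/2, (1 + 2F)/6, (1 + F)/4)``: the mean of the 4 diagonal cells, the
    mean of the 12 off-diagonal cells, and the mean of all 16 cells.
    """
    _check_f(F)
    half, quarter = _consts(F)
    if isinstance(F, Rational):
        cross = Fraction(1 + 2 * Fraction(F), 6)
    else:
        cross = (1 + 2 * F) / 6
    return half, cross, (1 + F) * quarter
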