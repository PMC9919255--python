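"""Exhaustive exact-rational verification layer.

Materializes the full with-replacement sample space of the four-genotype
array as genotype-count vectors with multinomial weights (C(m+3, 3) vectors
instead of 4**m tuples), and the stratified mating census behind the
synthetic-variety inbreeding formula.  Every closed form in the package is
arbitrated against these enumerations by exact Fraction equality; a float
anywhere in here is a bug.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial

from .exact import ExactProbability
from .gea import GEA_GENOTYPES, coancestry
from .inbreeding import decompose

__all__ = [
    "SampleOutcome",
    "enumerate_sample_space",
    "loss_census",
    "stratified_mating_ic",
]

_MAX_M = 30

# founder genes carried by each GEA genotype, indexed as (A1B1, A1B2, A2B1, A2B2)
_GENES = (
    frozenset({"A1", "B1"}),
    frozenset({"A1", "B2"}),
    frozenset({"A2", "B1"}),
    frozenset({"A2", "B2"}),
)


@dataclass(frozen=True)
class SampleOutcome:
    """One genotype-count vector with its multinomial ordering weight."""

    genotype_counts: tuple[int, int, int, int]
    weight: int
    gene_set: frozenset[str]
    genotype_set: frozenset[int]


def _check_m(m: int) -> None:
    if not isinstance(m, int) or not 1 <= m <= _MAX_M:
        raise ValueError(f"enumeration supports 1 <= m <= {_MAX_M}, got {m!r}")


def enumerate_sample_space(m: int) -> list[SampleOutcome]:
    """Weight-exact cover of the 4**m equally likely samples of size m."""
    _check_m(m)
    outcomes = []
    for c0 in range(m + 1):
        for c1 in range(m - c0 + 1):
            for c2 in range(m - c0 - c1 + 1):
                c3 = m - c0 - c1 - c2
                counts = (c0, c1, c2, c3)
                weight = factorial(m)
                for c in counts:
                    weight //= factorial(c)
                present = frozenset(i for i in range(4) if counts[i] > 0)
                genes = frozenset().union(*(_GENES[i] for i in present))
                outcomes.append(SampleOutcome(counts, weight, genes, present))
    return outcomes


def loss_census(
    m: int,
) -> tuple[ExactProbability, ExactProbability, ExactProbability, ExactProbability]:
    """(p_two_genes_lost, p_one_gene_lost, p_all_genes, p_all_genotypes).

    Classifies every sample by the number of distinct founder genes among
    its gametes (2, 3 or 4); the first three sum to 1 exactly.
    """
    _check_m(m)
    tn = 4**m
    w_two = w_one = w_all = w_geno = 0
    for out in enumerate_sample_space(m):
        n_genes = len(out.gene_set)
        if n_genes == 2:
            w_two += out.weight
        elif n_genes == 3:
            w_one += out.weight
        else:
            w_all += out.weight
        if len(out.genotype_set) == 4:
            w_geno += out.weight
    return (
        ExactProbability.from_ratio(w_two, tn),
        ExactProbability.from_ratio(w_one, tn),
        ExactProbability.from_ratio(w_all, tn),
        ExactProbability.from_ratio(w_geno, tn),
    )


def stratified_mating_ic(m: int, F, s: int = 1) -> Fraction:
    """Brute-force census behind the inbreeding formula.

    Builds the stratified sample — x complete sets of the four genotypes
    plus e distinct extras — averages `coancestry` over all m**2 ordered
    matings, then over all C(4, e) choices of the extras, and divides by s.
    Must equal `inbreeding.fsyn` exactly for every (m, F, s).
    """
    if not isinstance(s, int) or s < 1:
        raise ValueError(f"s must be a positive integer, got {s!r}")
    x, e = decompose(m)
    F = Fraction(F)
    total = Fraction(0)
    subsets = list(itertools.combinations(range(4), e))
    for extras in subsets:
        counts = [x + (1 if i in extras else 0) for i in range(4)]
        pair_sum = Fraction(0)
        for i in range(4):
            for j in range(4):
                if counts[i] == 0 or counts[j] == 0:
                    continue
                pair_sum += (
                    counts[i] * counts[j]
                    * coancestry(GEA_GENOTYPES[i], GEA_GENOTYPES[j], F)
                )
        total += pair_sum
    return total / (len(subsets) * m**2 * s)
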