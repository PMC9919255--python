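"""Exact probabilities of founder-gene loss in a finite sample.

Sampling ``m`` plants with replacement from the genotypic array of a single
cross can lose founder genes irreparably.  Two genes are lost exactly when
all ``m`` plants share one genotype:

    P2(m) = 4 (1/4)**m

One gene is lost exactly when the sample contains two genotypes that share a
gene — one ``v`` times and the other ``m - v`` times — which excludes the
pairs (A1B1, A2B2) and (A1B2, A2B1), whose two genotypes jointly carry all
four genes.  Each of the four gene-losing genotype pairs contributes
binomially, giving for m >= 3

    P1(m) = 8 * sum_{v=1}^{floor((m-1)/2)} C(m, v)/4**m      (odd m)
    P1(m) = 8 * sum_{v=1}^{m/2 - 1} C(m, v)/4**m
            + 4 * C(m, m/2)/4**m                             (even m)

with the base cases P1(1) = 0 and P1(2) = 1/2 handled directly.  The
equivalent closed form 4 (2**m - 2)/4**m and the exhaustive sample-space
census (`syncross.oracle`) serve as independent oracles in the test suite.

Several cells of the traditionally tabulated 3-decimal loss table conflict
with these formulas; :func:`reference_discrepancies` reports them, and the
formulas (arbitrated by exhaustive enumeration) always win.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from .exact import ExactProbability

__all__ = [
    "LossProbabilities",
    "two_gene_loss",
    "two_genotype_probability",
    "one_gene_loss",
    "loss_probabilities",
    "loss_table",
    "REFERENCE_LOSS_TABLE",
    "reference_discrepancies",
]


def _check_m(m: int) -> None:
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"sample size m must be a positive integer, got {m!r}")


@dataclass(frozen=True)
class LossProbabilities:
    """One-gene, two-gene and one-or-two-gene loss probabilities for one m."""

    m: int
    p_one: ExactProbability
    p_two: ExactProbability

    @property
    def p_any(self) -> ExactProbability:
        return ExactProbability(self.p_one.value + self.p_two.value)


def two_gene_loss(m: int) -> ExactProbability:
    """P(two genes lost) = 4 (1/4)**m: all m plants share one genotype."""
    _check_m(m)
    return ExactProbability.from_ratio(4, 4**m)


def two_genotype_probability(v: int, m: int) -> ExactProbability:
    """P(one specific ordered genotype pair occurs with counts (v, m - v)).

    C(m, v)/4**m, for 1 <= v <= m - 1.
    """
    _check_m(m)
    if m < 2:
        raise ValueError("two-genotype samples require m >= 2")
    if not 1 <= v <= m - 1:
        raise ValueError(f"v must satisfy 1 <= v <= m-1, got v={v}, m={m}")
    return ExactProbability.from_ratio(comb(m, v), 4**m)


def one_gene_loss(m: int) -> ExactProbability:
    """P(exactly one gene lost) in an m-sample, exact.

    Sums the two-genotype sample probabilities over the four gene-losing
    genotype pairs; 8 ordered (v, m-v) terms per unordered split, with the
    balanced split of even m counted once per pair (factor 4).
    """
    _check_m(m)
    if m == 1:
        return ExactProbability(Fraction(0))
    if m == 2:
        # the four gene-losing pairs, each in two orders: (2 * 4)/4**2
        return ExactProbability.from_ratio(8, 16)
    total = Fraction(0)
    if m % 2 == 0:
        for v in range(1, m // 2):
            total += 8 * two_genotype_probability(v, m).value
        total += 4 * two_genotype_probability(m // 2, m).value
    else:
        for v in range(1, (m - 1) // 2 + 1):
            total += 8 * two_genotype_probability(v, m).value
    return ExactProbability(total)


def loss_probabilities(m: int) -> LossProbabilities:
    return LossProbabilities(m, one_gene_loss(m), two_gene_loss(m))


def loss_table(m_values, decimals: int | None = 3) -> list[LossProbabilities]:
    """Loss probabilities for each requested sample size.

    ``decimals`` is kept for interface symmetry with the table writers; the
    returned objects are exact and rounding happens at display time.
    """
    m_values = list(m_values)
    if not m_values:
        raise ValueError("m_values must be non-empty")
    return [loss_probabilities(m) for m in m_values]


#: Previously tabulated 3-decimal loss probabilities for m = 1..12 (rows
#: P1, P2, P1_2).  Kept verbatim for arbitration: several cells conflict
#: with the defining formulas and the exhaustive census — see
#: :func:`reference_discrepancies`.
REFERENCE_LOSS_TABLE: dict[str, tuple[float, ...]] = {
    "P1": (0.000, 0.500, 0.375, 0.227, 0.118, 0.061, 0.037, 0.016, 0.009, 0.004, 0.002, 0.000),
    "P2": (1.000, 0.250, 0.063, 0.016, 0.004, 0.001, 0.010, 0.000, 0.000, 0.000, 0.000, 0.000),
    "P1_2": (1.000, 0.750, 0.438, 0.235, 0.122, 0.062, 0.047, 0.016, 0.009, 0.004, 0.002, 0.000),
}


def reference_discrepancies() -> list[tuple[str, int, float, float]]:
    """Cells of the tabulated reference that conflict with the formulas.

    Returns ``(row, m, tabulated, computed)`` for every cell whose half-up
    3-decimal formula value differs from the tabulated one.
    """
    out = []
    for i, m in enumerate(range(1, 13)):
        lp = loss_probabilities(m)
        computed = {"P1": lp.p_one, "P2": lp.p_two, "P1_2": lp.p_any}
        for row, printed in REFERENCE_LOSS_TABLE.items():
            got = computed[row].round(3)
            if abs(got - printed[i]) > 1e-9:
                out.append((row, m, printed[i], got))
    return out
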