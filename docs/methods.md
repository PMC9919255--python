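# Methods

## The model

A synthetic variety is formed by one round of random mating among the plants
representing `s` single-cross maize hybrids. Each single cross is the F1 of
two inbred lines, `A1A2 x B1B2`; the 2s lines are mutually unrelated and
share a common inbreeding coefficient `F` — the probability that a line's
two genes at the locus are identical by descent (IBD), so `P(A1 ≡ A2) = F`.
A single cross segregates into exactly four genotypes, `A1B1, A1B2, A2B1,
A2B2`, each at frequency 1/4 (its genotypic array). Each parent is
represented by a finite sample of `m` plants drawn from that array; the
synthetic's expected inbreeding and its exposure to genetic erosion (loss
of founder genes or genotypes from a parent's sample) are all functions of
`(m, F, s)`.

Everything rests on a single 4 x 4 coancestry kernel: the progeny of a
mating between two array genotypes has inbreeding coefficient 1/2 if the
genotypes share both gene labels (selfing, or two plants of the same
genotype), `(1+F)/4` if they share exactly one, and `F/2` if they share
none. The kernel's off-diagonal mean is `(1+2F)/6` and its grand mean
`(1+F)/4`; these two margins are what the closed forms are assembled from.

## Closed forms

**Inbreeding coefficient.** Writing `m = 4x + e` (`x` complete sets of the
four genotypes plus `e in {0,1,2,3}` leftover plants of distinct
genotypes), the expected inbreeding coefficient of the synthetic is

    F_syn = [ m/2 + (12x + e(e-1))(1+2F)/6 + (16x(x-1) + 8xe)(1+F)/4 ] / (m^2 s)

— the `m` selfings, the intragroup crosses (within each group of four, and
among the `e` extras), and the intergroup crosses, averaged over all `m^2`
ordered intraparental matings. Interparental matings contribute nothing
because the lines of different crosses are unrelated. `F_syn` collapses to
the plateau `(1+F)/(4s)` whenever `4 | m`, and to `1/(2s)` whenever `m = 1`
or `F = 1`.

**Genotype inclusion.** Under with-replacement sampling, a sample of size
`m` contains all four genotypes iff its counts form a partition of `m` into
four positive parts (a *frequency set*). A frequency set with counts
`(f1..f4)` contributes `NF * NP / 4^m`, with `NF = m!/(f1!f2!f3!f4!)` the
orderings of one count assignment and `NP = 4!/(prod P_l!)` the distinct
assignments of counts to genotypes (`P_l` = multiplicities of the distinct
count values). The enumeration route is primary; the inclusion–exclusion
closed form `1 - 4(3/4)^m + 6(2/4)^m - 4(1/4)^m` is retained purely as an
independent cross-check and agrees exactly for every m tested (1..30).

**Gene loss.** Two founder genes are lost iff the whole sample shares one
genotype: `P2(m) = 4(1/4)^m`. Exactly one gene is lost iff the sample
contains two genotypes sharing a gene, one `v` times and one `m - v` times
— four such genotype pairs exist (the pairs `{A1B1, A2B2}` and
`{A1B2, A2B1}` jointly carry all four genes and are excluded). Summing the
binomial terms `C(m, v)/4^m` over the admissible splits, with the balanced
split of even `m` counted once per pair, gives `P1(m)`; `m = 1` and
`m = 2` are explicit base cases (the general sums are stated for m >= 3).
The algebraic simplification `P1(m) = 4(2^m - 2)/4^m` is used only as a
test oracle, never as the implementation.

## Two sampling models, kept deliberately separate

The inbreeding formula follows from a *stratified* sample composition
(`x` complete genotype sets plus `e` distinct extras); the erosion
probabilities follow from independent *with-replacement* (multinomial)
sampling, under which the expected inbreeding would instead be
`[m/2 + m(m-1)(1+F)/4]/(m^2 s)` — strictly larger whenever `m > 1` and
`F < 1` (0.30 vs 0.26 at m=5, F=0). Rather than guessing a single intended
model, both are implemented: the closed form is pinned to the stratified
composition (the only one consistent with its `e(e-1)(1+2F)/6` term, which
forces the extras to be distinct, i.e. drawn without replacement), and the
simulator exposes both as modes so the divergence is measured, not assumed.
The stratified census averages over all `C(4, e)` choices of the extras'
genotypes; for a fixed choice the extras' pairwise mean is generally not
`(1+2F)/6`, so this averaging is part of the model, not a convenience.

## Verification layers

1. **Exhaustive census (exact).** The 4^m sample space is enumerated as
   genotype-count vectors with multinomial weights (C(m+3,3) vectors, so
   m up to 30 is desk-scale), and each outcome classified by its founder
   genes and genotypes present. Inclusion and loss formulas must agree with
   the census as exact rationals. The stratified mating census averages the
   coancestry kernel over all m^2 ordered matings and all extras choices
   and must equal the inbreeding formula exactly; the test grid covers
   m = 1..12, six F values, s in {1, 2, 5}.
2. **Gene-dropping Monte Carlo (stochastic).** Founder labels are dropped
   through one generation: each line gets two labels, collapsed with
   probability `F` per line per replicate (a pure Bernoulli realization, so
   the replicate average recovers `F`; fractional IBD weights were rejected
   to keep the simulator a genuine gene-dropping process); samples are
   built in either mode; progeny are formed from uniformly drawn ordered
   parent pairs (selfing included, matching the `m` selfings in the m^2
   accounting) with one random gamete each. A progeny is IBD iff its two
   gametes carry the same label. Stochastic checks use 3-standard-error
   bands at fixed seeds, with the standard error taken across replicate
   means. Restricting mating to different parents yields exactly zero IBD,
   confirming that only intraparental mating contributes.

What the simulator emulates is exactly the single-locus, one-generation
model: no linkage, no selection, no mutation, no multi-generation drift,
and no relatedness between lines. Passing stochastic tests therefore
validates the algebra of the closed forms under the model's own
assumptions; they say nothing about how real maize populations deviate
from those assumptions (multi-locus structure, assortative flowering,
unequal gamete contributions).

## Numerical policy

All probabilities and coefficients are exact `fractions.Fraction` values
end to end; floats exist only behind explicit display calls. Rounding is
half-up (not banker's) at the requested precision, applied to the exact
rational — this is the convention under which the reference tables were
evidently produced where they are self-consistent. Oracle comparisons are
exact rational equality; a float inside the oracle layer is treated as a
bug.

Two convention points required a decision:

- **Minimum adequate sample size.** The exact inclusion probability at
  m = 15 is 0.94673..., first exceeding 0.95 at m = 16; the traditional
  answer of 15 holds only after rounding each probability half-up to two
  decimals. `min_m_for_inclusion` takes an explicit `rounding_decimals`
  argument so both conventions are first-class; thresholds given as floats
  are read at decimal face value (0.95 means 19/20) because the comparison
  is exact.
- **Reference loss-table conflicts.** The traditionally tabulated
  3-decimal loss table conflicts with its own defining formulas at several
  cells (P1 at m = 4, 5, 7, 9, 12; P2 at m = 7; and the P1+P2 row at those
  m). The exhaustive census sides with the formulas in every case, so the
  package reports these cells as discrepancies
  (`gene_loss.reference_discrepancies()`, annotated in the `table7`
  output) and never matches them.

## Parameters and defaults

| parameter | meaning | domain | default |
|---|---|---|---|
| `m` | plants sampled per parent single cross | integer >= 1 | — |
| `F` | inbreeding coefficient of the parent lines | [0, 1], any rational/float | — |
| `s` | number of parent single crosses | integer >= 1 | 1 |
| `mode` | sampling model | `stratified` / `multinomial` | `stratified` |
| `replicates`, `progeny_per_replicate` | Monte Carlo sizes | >= 1 | 1000 / 1000 |

`F` is accepted anywhere in [0, 1], not only the five tabulated values,
since the closed form is stated for the full interval. Stochastic
validation sizes are 10^6 progeny (1000 x 1000) for IBD estimates and 10^5
single-draw replicates for erosion rates; at these sizes the 3-SE bands are
a few parts in 10^3, tight enough to separate the two sampling models at
m = 5, F = 0.

## Known limitations

Single locus, one generation, unrelated lines, equal genotype frequencies
in every parent array; enumeration is capped at m = 30 (the count-vector
space beyond that is still polynomial but no reference quantity needs it);
gene-loss probabilities are defined only under the multinomial model — the
stratified composition cannot lose genes by construction.
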