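# syncross

Exact finite-sample genetics of **synthetic varieties formed from
single-cross hybrids**.

When a maize synthetic variety is built by random mating of `s` single
crosses (each the F1 of two unrelated inbred lines with inbreeding
coefficient `F`), and each cross is represented by only `m` plants, the
finite sample size drives two things breeders care about: the inbreeding
coefficient of the synthetic, and the risk of *genetic erosion* — founder
genes or genotypes missing from a parent's sample. `syncross` computes all
of these exactly (rational arithmetic end to end), verifies every closed
form against exhaustive enumeration, and validates the model by Monte
Carlo gene dropping.

## The core results

With `m = 4x + e` (`x` complete sets of the four single-cross genotypes
`A1B1, A1B2, A2B1, A2B2`, plus `e` distinct extras), the synthetic's
inbreeding coefficient is

    F_syn = [ m/2 + (12x + e(e-1))(1+2F)/6 + (16x(x-1) + 8xe)(1+F)/4 ] / (m^2 s)

which plateaus at `(1+F)/(4s)` whenever `m` is a multiple of 4 and equals
`1/(2s)` whenever `m = 1` or `F = 1`. Under with-replacement sampling, the
probability that a sample of `m` includes all four genotypes is

    P(inclusion) = sum over partitions of m into 4 positive parts of NF * NP / 4^m

(`NF` the multinomial orderings, `NP` the distinct count-to-genotype
assignments), and the probabilities of losing two or exactly one founder
gene are `P2 = 4(1/4)^m` and a sum of binomial terms over the four
gene-losing genotype pairs. See `docs/methods.md` for the full model,
conventions, and the places where the traditionally tabulated values
conflict with their own formulas (the package arbitrates by exhaustive
census and reports, rather than matches, those cells).

## Worked example

```sh
$ syncross fsyn --m 7 --f 0 --exact
25/98
```

A sample of 7 plants (one full genotype group plus 3 extras) from a single
cross of fully outbred lines gives F_syn = 25/98 ≈ 0.2551 — above the
m-multiple-of-4 plateau of 0.25, because unequal genotype frequencies make
same-genotype matings more frequent.

```sh
$ syncross simulate --m 5 --f 0 --replicates 1000 --progeny 1000 --seed 42
quantity        estimate        se        exact
mean_ibd        0.259892        0.000437  0.260000
genotype_inclusion  1.000000    0.000000  0.234375
one_gene_loss   0.000000        0.000000  0.117188
two_gene_loss   0.000000        0.000000  0.003906
```

One million gene-dropped progeny reproduce the closed form 0.2600 within a
standard error. The inclusion/loss columns show their exact multinomial
values for reference; in the default `stratified` mode the sample always
contains all four genotypes by construction (rates 1 and 0) — switch
`--mode multinomial` to simulate with-replacement sampling, where those
probabilities bite and the mean IBD rises to `[m/2 + m(m-1)(1+F)/4]/(m^2 s)`.

Other entry points: `syncross table2` (the 24 x 5 inbreeding grid),
`syncross table4` (per-frequency-set inclusion breakdown), `syncross
table7` (loss table with discrepancy annotations), `syncross verify` (the
full exact cross-check grid; non-zero exit on any mismatch).

As a library:

```python
>>> from syncross import fsyn, inclusion_probability, min_m_for_inclusion
>>> fsyn(7, 0, 1).value
Fraction(25, 98)
>>> inclusion_probability(15).float_view
0.9467292577028275
>>> min_m_for_inclusion(0.95, rounding_decimals=2), min_m_for_inclusion(0.95)
(15, 16)
```

The exact inclusion probability first reaches 0.95 at m = 16; the
traditional answer of 15 holds under 2-decimal rounding. Both conventions
are exposed explicitly.

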