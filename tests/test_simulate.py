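"""Gene-dropping simulator: reproducibility and convergence to closed forms.

Stochastic assertions use 3-standard-error bands at fixed seeds.
"""

from fractions import Fraction

import numpy as np
import pytest

from syncross import (
    SimulationConfig,
    SyntheticDesign,
    fsyn,
    inclusion_probability,
    multinomial_expected_ibd,
    run,
    two_gene_loss,
)
from syncross.simulate import build_sample, drop_founders, random_mating_ibd


def within_3se(estimate, exact, se):
    return abs(estimate - float(exact)) <= 3 * max(se, 1e-12)


class TestDropFounders:
    def test_f_zero_all_distinct(self):
        rng = np.random.default_rng(0)
        labels = drop_founders(3, 0.0, rng, replicates=50)
        for rep in labels:
            assert len(set(rep.ravel().tolist())) == 12

    def test_f_one_within_line_identical(self):
        rng = np.random.default_rng(0)
        labels = drop_founders(2, 1.0, rng, replicates=20)
        assert (labels[:, :, 0] == labels[:, :, 1]).all()

    def test_lines_never_share_labels(self):
        rng = np.random.default_rng(1)
        labels = drop_founders(4, 0.5, rng, replicates=100)
        for rep in labels:
            sets = [set(line.tolist()) for line in rep]
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    assert not (sets[i] & sets[j])

    def test_intermediate_f_binomial(self):
        rng = np.random.default_rng(2)
        n = 20_000
        labels = drop_founders(1, 0.5, rng, replicates=n)
        freq = (labels[:, :, 0] == labels[:, :, 1]).mean()
        se = np.sqrt(0.25 / (2 * n))
        assert within_3se(freq, 0.5, se)

    def test_domain(self):
        with pytest.raises(ValueError):
            drop_founders(1, 1.5, np.random.default_rng(0))


class TestBuildSample:
    def test_stratified_multiple_of_four(self):
        rng = np.random.default_rng(3)
        s = build_sample(SyntheticDesign(8, 0.0), "stratified", rng, replicates=10)
        for rep in s[:, 0, :]:
            assert sorted(np.bincount(rep, minlength=4)) == [2, 2, 2, 2]

    def test_stratified_extras_distinct(self):
        rng = np.random.default_rng(3)
        s = build_sample(SyntheticDesign(7, 0.0), "stratified", rng, replicates=200)
        for rep in s[:, 0, :]:
            assert sorted(np.bincount(rep, minlength=4)) == [1, 2, 2, 2]

    def test_stratified_extras_uniform_over_choices(self):
        rng = np.random.default_rng(4)
        s = build_sample(SyntheticDesign(5, 0.0), "stratified", rng, replicates=20_000)
        extra = s[:, 0, 4]
        freq = np.bincount(extra, minlength=4) / len(extra)
        se = np.sqrt(0.25 * 0.75 / len(extra))
        assert all(within_3se(f, 0.25, se) for f in freq)

    def test_multinomial_inclusion_rate(self):
        rng = np.random.default_rng(5)
        n = 50_000
        s = build_sample(SyntheticDesign(4, 0.0), "multinomial", rng, replicates=n)
        counts = (s[:, 0, :, None] == np.arange(4)).sum(axis=1)
        rate = (counts > 0).all(axis=1).mean()
        exact = 24 / 256
        se = np.sqrt(exact * (1 - exact) / n)
        assert within_3se(rate, exact, se)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            build_sample(SyntheticDesign(4, 0.0), "bootstrap", np.random.default_rng(0))


class TestRun:
    def test_reproducible(self):
        cfg = SimulationConfig(SyntheticDesign(5, 0.5, 2), "stratified", 50, 200, seed=11)
        r1, r2 = run(cfg), run(cfg)
        assert r1 == r2

    def test_seed_changes_result(self):
        base = SyntheticDesign(5, 0.5, 2)
        r1 = run(SimulationConfig(base, "stratified", 50, 200, seed=11))
        r2 = run(SimulationConfig(base, "stratified", 50, 200, seed=12))
        assert r1.mean_ibd != r2.mean_ibd

    @pytest.mark.parametrize(
        "m,F,s",
        [(1, Fraction(0), 1), (5, Fraction(0), 1), (7, Fraction(1, 2), 1), (4, Fraction(1, 2), 3)],
    )
    def test_stratified_ibd_converges_to_closed_form(self, m, F, s):
        cfg = SimulationConfig(SyntheticDesign(m, F, s), "stratified", 400, 1500, seed=101)
        res = run(cfg)
        assert within_3se(res.mean_ibd, fsyn(m, F, s).value, res.se_ibd)

    def test_f1_zero_variance_across_genotype_choice(self):
        # at F=1 every mating has coancestry 1/2 whatever the sample looks like
        cfg = SimulationConfig(SyntheticDesign(4, 1.0, 1), "stratified", 200, 800, seed=7)
        res = run(cfg)
        assert within_3se(res.mean_ibd, 0.5, res.se_ibd)

    def test_multinomial_ibd_matches_own_mean_not_stratified(self):
        """With-replacement sampling has a strictly larger expected IBD than
        the stratified composition; the simulator resolves the difference."""
        m, F = 5, Fraction(0)
        cfg = SimulationConfig(SyntheticDesign(m, F, 1), "multinomial", 600, 1500, seed=23)
        res = run(cfg)
        analytic = multinomial_expected_ibd(m, F)  # 3/10
        assert within_3se(res.mean_ibd, analytic, res.se_ibd)
        # 0.30 vs 0.26: the two models are separated by far more than 3 SE
        assert res.mean_ibd - float(fsyn(m, F, 1).value) > 3 * res.se_ibd

    def test_multinomial_erosion_rates(self):
        cfg = SimulationConfig(SyntheticDesign(7, 0.0, 1), "multinomial", 40_000, 1, seed=31)
        res = run(cfg)
        inc = inclusion_probability(7).float_view
        assert within_3se(res.genotype_inclusion_rate, inc, res.rate_se(inc))
        cfg2 = SimulationConfig(SyntheticDesign(2, 0.0, 1), "multinomial", 40_000, 1, seed=31)
        res2 = run(cfg2)
        p2 = two_gene_loss(2).float_view
        assert within_3se(res2.two_gene_loss_rate, p2, res2.rate_se(p2))
        assert within_3se(res2.one_gene_loss_rate, 0.5, res2.rate_se(0.5))

    def test_rate_partition(self):
        cfg = SimulationConfig(SyntheticDesign(3, 0.0, 1), "multinomial", 5000, 1, seed=2)
        res = run(cfg)
        total = res.one_gene_loss_rate + res.two_gene_loss_rate + res.all_genes_rate
        assert total == pytest.approx(1.0)


class TestInterparentalCrosses:
    def test_contribute_zero_ibd(self):
        """Lines of different single crosses are unrelated, so matings
        restricted to different parents can never produce IBD progeny."""
        rng = np.random.default_rng(13)
        design = SyntheticDesign(4, 0.75, 3)
        founders = drop_founders(design.s, design.F, rng, replicates=50)
        samples = build_sample(design, "stratified", rng, replicates=50)
        from syncross.simulate import _plant_labels

        lab_a, lab_b = _plant_labels(samples, founders, design.s)
        parent = np.repeat(np.arange(design.s), design.m)
        rates = random_mating_ibd(
            lab_a, lab_b, 500, rng, parent_of_plant=parent, exclude_same_parent=True
        )
        assert (rates == 0).all()
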