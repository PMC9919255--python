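"""Monte Carlo gene-dropping validation of the closed-form results.

One replicate of the simulator plays out the formation of a synthetic
variety at a single locus:

1. *Founder drop* — each of the 2s parent lines receives two founder
   labels; with probability ``F`` (independently per line, per replicate)
   the two labels coincide, realizing the line's inbreeding.  Labels never
   coincide across lines (the lines are unrelated).
2. *Sample construction* — ``m`` plants per single cross, either by the
   stratified composition behind the closed-form inbreeding coefficient
   (x complete sets of the four genotypes plus e distinct extras drawn
   without replacement), or as ``m`` independent uniform draws from the
   four genotypes (the with-replacement multinomial model).
3. *Random mating* — ordered parent pairs drawn uniformly from all
   (ms)**2 pairs (selfing included), one random gamete from each; a progeny
   is identical by descent iff its two gametes carry the same founder label.

The replicate-averaged IBD fraction is an unbiased estimator of the
expected inbreeding coefficient of the sampling model in force; genotype
inclusion and gene-loss rates are tallied per parent sample.  Everything is
vectorised numpy and deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .inbreeding import SyntheticDesign

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "drop_founders",
    "build_sample",
    "random_mating_ibd",
    "multinomial_expected_ibd",
    "run",
]

MODES = ("stratified", "multinomial")


@dataclass(frozen=True)
class SimulationConfig:
    """Gene-dropping run description: design, sampling model, sizes, seed."""

    design: SyntheticDesign
    mode: str = "stratified"
    replicates: int = 1000
    progeny_per_replicate: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.replicates < 1 or self.progeny_per_replicate < 1:
            raise ValueError("replicates and progeny_per_replicate must be >= 1")


@dataclass(frozen=True)
class SimulationResult:
    """Replicate-averaged estimates with standard errors.

    ``mean_ibd`` estimates the expected progeny inbreeding coefficient of
    the configured sampling model; the rates partition parent samples by
    genotype inclusion and by the number of founder genes retained.
    """

    config: SimulationConfig
    mean_ibd: float
    se_ibd: float
    genotype_inclusion_rate: float
    one_gene_loss_rate: float
    two_gene_loss_rate: float
    all_genes_rate: float
    rate_n: int

    def rate_se(self, rate: float) -> float:
        return float(np.sqrt(rate * (1 - rate) / self.rate_n))


def drop_founders(s: int, F, rng: np.random.Generator, replicates: int = 1) -> np.ndarray:
    """Founder labels for the 2s lines, shape (replicates, 2s, 2).

    Line ``j`` carries labels (2j, 2j+1); with probability ``F`` its second
    label collapses onto the first (the two genes identical by descent).
    """
    if not 0 <= F <= 1:
        raise ValueError(f"F must be in [0, 1], got {F}")
    n_lines = 2 * s
    base = 2 * np.arange(n_lines)
    labels = np.empty((replicates, n_lines, 2), dtype=np.int64)
    labels[:, :, 0] = base
    ibd = rng.random((replicates, n_lines)) < float(F)
    labels[:, :, 1] = np.where(ibd, base, base + 1)
    return labels


def build_sample(
    design: SyntheticDesign,
    mode: str,
    rng: np.random.Generator,
    replicates: int = 1,
) -> np.ndarray:
    """Genotype indices (0..3 = A1B1, A1B2, A2B1, A2B2), shape (R, s, m)."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    m, s = design.m, design.s
    if mode == "multinomial":
        return rng.integers(0, 4, size=(replicates, s, m))
    x, e = design.x, design.e
    full = np.tile(np.arange(4), x)
    out = np.empty((replicates, s, m), dtype=np.int64)
    out[:, :, : 4 * x] = full
    if e:
        # e distinct extras: first e entries of a random permutation of 0..3
        order = np.argsort(rng.random((replicates, s, 4)), axis=-1)
        out[:, :, 4 * x :] = order[:, :, :e]
    return out


def _plant_labels(
    samples: np.ndarray, founders: np.ndarray, s: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-plant founder labels (labA, labB), each shape (R, ms)."""
    R = samples.shape[0]
    m = samples.shape[2]
    flat = samples.reshape(R, s * m)
    parent = np.repeat(np.arange(s), m)[None, :]  # (1, ms)
    r_idx = np.arange(R)[:, None]
    lab_a = founders[r_idx, 2 * parent, flat >> 1]
    lab_b = founders[r_idx, 2 * parent + 1, flat & 1]
    return lab_a, lab_b


def random_mating_ibd(
    lab_a: np.ndarray,
    lab_b: np.ndarray,
    progeny_n: int,
    rng: np.random.Generator,
    parent_of_plant: np.ndarray | None = None,
    exclude_same_parent: bool = False,
) -> np.ndarray:
    """Per-replicate fraction of IBD progeny under uniform random mating.

    Draws ``progeny_n`` ordered plant pairs per replicate (selfing allowed),
    one random gamete each.  With ``exclude_same_parent`` the second plant
    is drawn from a different single cross (requires ``parent_of_plant`` and
    s >= 2) — such interparental crosses can never be IBD.
    """
    if lab_a.size == 0:
        raise ValueError("empty sample")
    R, n_plants = lab_a.shape
    i = rng.integers(0, n_plants, size=(R, progeny_n))
    j = rng.integers(0, n_plants, size=(R, progeny_n))
    if exclude_same_parent:
        if parent_of_plant is None:
            raise ValueError("exclude_same_parent requires parent_of_plant")
        s = int(parent_of_plant.max()) + 1
        if s < 2:
            raise ValueError("exclude_same_parent requires s >= 2")
        m = n_plants // s
        # different parent chosen uniformly, then a plant within it
        shift = 1 + rng.integers(0, s - 1, size=(R, progeny_n))
        other = (parent_of_plant[i] + shift) % s
        j = other * m + rng.integers(0, m, size=(R, progeny_n))
    pick_i = rng.integers(0, 2, size=(R, progeny_n))
    pick_j = rng.integers(0, 2, size=(R, progeny_n))
    g1 = np.where(pick_i == 0, np.take_along_axis(lab_a, i, 1), np.take_along_axis(lab_b, i, 1))
    g2 = np.where(pick_j == 0, np.take_along_axis(lab_a, j, 1), np.take_along_axis(lab_b, j, 1))
    return (g1 == g2).mean(axis=1)


def multinomial_expected_ibd(m: int, F, s: int = 1) -> Fraction:
    """Expected IBD under independent with-replacement sampling.

    [m/2 + m(m-1)(1+F)/4] / (m^2 s): the analytic mean of the multinomial
    model, which exceeds the stratified closed form whenever m > 1, F < 1.
    It is derived independently of the simulator and of the stratified
    formula, and serves as the multinomial-mode oracle.
    """
    F = Fraction(F)
    return (Fraction(m, 2) + m * (m - 1) * (1 + F) / 4) / (m**2 * s)


def _erosion_rates(samples: np.ndarray) -> tuple[float, float, float, float]:
    """Inclusion / gene-retention rates over all (R*s) parent samples."""
    R, s, m = samples.shape
    counts = (samples[..., None] == np.arange(4)).sum(axis=2)  # (R, s, 4)
    has = counts > 0
    inclusion = has.all(axis=-1).mean()
    n_genes = (
        (has[..., 0] | has[..., 1]).astype(int)   # A1 in A1B1 or A1B2
        + (has[..., 2] | has[..., 3]).astype(int)  # A2
        + (has[..., 0] | has[..., 2]).astype(int)  # B1
        + (has[..., 1] | has[..., 3]).astype(int)  # B2
    )
    return (
        float(inclusion),
        float((n_genes == 3).mean()),
        float((n_genes == 2).mean()),
        float((n_genes == 4).mean()),
    )


def run(config: SimulationConfig) -> SimulationResult:
    """Execute a full gene-dropping run; bit-reproducible given the seed."""
    design = config.design
    rng = np.random.default_rng(config.seed)
    R, s = config.replicates, design.s
    founders = drop_founders(s, design.F, rng, replicates=R)
    samples = build_sample(design, config.mode, rng, replicates=R)
    lab_a, lab_b = _plant_labels(samples, founders, s)
    per_rep = random_mating_ibd(lab_a, lab_b, config.progeny_per_replicate, rng)
    mean_ibd = float(per_rep.mean())
    if R > 1:
        se_ibd = float(per_rep.std(ddof=1) / np.sqrt(R))
    else:
        se_ibd = float(
            np.sqrt(mean_ibd * (1 - mean_ibd) / config.progeny_per_replicate)
        )
    inclusion, one_loss, two_loss, all_genes = _erosion_rates(samples)
    return SimulationResult(
        config=config,
        mean_ibd=mean_ibd,
        se_ibd=se_ibd,
        genotype_inclusion_rate=inclusion,
        one_gene_loss_rate=one_loss,
        two_gene_loss_rate=two_loss,
        all_genes_rate=all_genes,
        rate_n=R * s,
    )
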