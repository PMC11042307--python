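"""Synthetic cohorts with known genetic architecture.

Three generators cover the study conditions the method is validated
against: (i) a Fisher-type cohort with a constant allelic effect and
optional dominance on a Hardy-Weinberg genotype (the paraboloid-path
case), (ii) theoretic pure-null SNPs with fixed microstate counts (the
permutation-null calibration set, six named presets), and (iii) a
sign-flipping cohort in which a latent half/half subpopulation reverses
the allelic effect and offsets the residual range, producing sigmoid
paths whose homozygote group means are nearly equal -- invisible to
mean-based single-marker tests.

Genotype letters are emitted as AA / AG / GG so that encoding round-trips
the simulated microstate truth (+1 / 0 / -1) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import GenotypeMatrix, MicrostateVector, SnpRecord

#: theoretic null SNPs (N+, N0, N-), each with N = 565; consecutive presets
#: move 100 microstates from the '-1' class into the '0' class.
THEORETIC_PRESETS = {
    "SNP1": (25, 25, 515),
    "SNP2": (25, 125, 415),
    "SNP3": (25, 225, 315),
    "SNP4": (25, 325, 215),
    "SNP5": (25, 425, 115),
    "SNP6": (25, 525, 15),
}

_LETTERS = {1: ("A", "A"), 0: ("A", "G"), -1: ("G", "G")}


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    microstates: list  # MicrostateVector truth per SNP
    phenotype: np.ndarray
    truth: pd.DataFrame  # per-SNP: snp_id, architecture, a_true, d_true
    seed: object


def _hw_microstates(n, allele_freq, rng):
    """Microstates under Hardy-Weinberg proportions (p^2, 2pq, q^2).

    ``allele_freq`` is the frequency p of the allele whose homozygote is
    the +1 class (AA)."""
    if not 0 < allele_freq < 1:
        raise ValueError(f"allele_freq must be in (0,1), got {allele_freq}")
    p = allele_freq
    u = rng.random(n)
    m = np.where(u < p * p, 1, np.where(u < p * p + 2 * p * (1 - p), 0, -1))
    return m.astype(np.int8)


def _cohort(snp_specs, microstate_mat, phenotype, truth_rows, seed):
    n = microstate_mat.shape[1]
    ids = [f"ind{k:04d}" for k in range(n)]
    snps = []
    vectors = []
    for (snp_id, chrom, pos), m in zip(snp_specs, microstate_mat):
        calls = [_LETTERS[int(v)] for v in m]
        snps.append(SnpRecord(snp_id, chrom, pos, calls))
        vectors.append(MicrostateVector(snp_id, m.astype(float)))
    truth = pd.DataFrame(
        truth_rows, columns=["snp_id", "architecture", "a_true", "d_true"]
    )
    return SyntheticCohort(
        GenotypeMatrix(ids, snps), vectors, np.asarray(phenotype, float), truth, seed
    )


def simulate_fisher_cohort(
    n: int = 1000,
    allele_freq: float = 0.8,
    phen_mean: float = 68.0,
    phen_sd: float = 2.0,
    a_true: float | None = None,
    d_true: float = 0.0,
    seed=None,
    snp_id: str = "fisher_snp",
) -> SyntheticCohort:
    """Constant-allelic-effect cohort on a Hardy-Weinberg genotype.

    Defaults are the classical demonstration setting: n = 1000, genotype
    class frequencies (0.64, 0.32, 0.04), phenotype mean 68 and sd 2, gene
    effect equal to the phenotype sd, no dominance. Each microstate group
    is normally distributed with sd ``phen_sd`` around its shifted mean
    (per-group normality convention; the marginal sd then slightly exceeds
    ``phen_sd`` by the genetic variance).
    """
    if a_true is None:
        a_true = phen_sd
    rng = np.random.default_rng(seed)
    m = _hw_microstates(n, allele_freq, rng)
    y = phen_mean + a_true * m + d_true * (m == 0) + rng.normal(0.0, phen_sd, n)
    return _cohort(
        [(snp_id, "1", 1)],
        m[None, :],
        y,
        [(snp_id, "linear", a_true, d_true)],
        seed,
    )


def simulate_theoretic_snp(counts, seed=None) -> np.ndarray:
    """Uniformly random arrangement of exact microstate counts (pure null).

    ``counts`` may be a (N+, N0, N-) tuple or a preset name from
    ``THEORETIC_PRESETS``."""
    from .null_model import permute_string

    if isinstance(counts, str):
        counts = THEORETIC_PRESETS[counts]
    rng = np.random.default_rng(seed)
    return permute_string(tuple(counts), rng)


def simulate_sign_flip_cohort(
    n: int = 500,
    allele_freq: float = 0.5,
    a_true: float = 3.0,
    noise_sd: float = 1.0,
    seed=None,
    snp_id: str = "signflip_snp",
    subpop_half_gap: float | None = None,
) -> SyntheticCohort:
    """Scale-dependent (sign-flipping) effect: sigmoid path, GWAS-blind.

    Each individual belongs to a latent subpopulation s = +/-1 with equal
    probability. The phenotype is s*half_gap + s*a_true*m + noise, so the
    two subpopulations occupy the lower and upper residual ranges while
    the allelic effect points in opposite directions within them: group
    means coincide in expectation but phenotype ranking segregates
    microstates into a sigmoid path. half_gap defaults to
    a_true + 4*noise_sd (non-overlapping subpopulation ranges).
    """
    rng = np.random.default_rng(seed)
    if subpop_half_gap is None:
        subpop_half_gap = a_true + 4.0 * noise_sd
    m = _hw_microstates(n, allele_freq, rng)
    s = rng.choice((-1.0, 1.0), size=n)
    y = s * subpop_half_gap + s * a_true * m + rng.normal(0.0, noise_sd, n)
    return _cohort(
        [(snp_id, "1", 1)],
        m[None, :],
        y,
        [(snp_id, "sign_flip", a_true, 0.0)],
        seed,
    )


def simulate_genome_panel(
    m_snps: int = 200,
    n: int = 565,
    fraction_causal: float = 0.05,
    architectures=("linear", "sign_flip"),
    seed=None,
    n_chromosomes: int = 3,
    allele_freq_range=(0.2, 0.8),
    effect_size: float = 0.5,
    noise_sd: float = 1.0,
    subpop_half_gap: float = 4.0,
) -> SyntheticCohort:
    """Mixed panel of null/causal SNPs with one shared phenotype.

    Causal SNPs are split among the requested architectures. Linear SNPs
    add ``effect_size * m`` to the phenotype; sign-flip SNPs add
    ``s * effect_size * m`` where s is a shared latent subpopulation that
    also contributes ``s * subpop_half_gap`` (so sign-flip effects track
    the residual scale). SNPs are independent (no LD), laid out on fake
    chromosomes with increasing positions.
    """
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*allele_freq_range, size=m_snps)
    microstates = np.stack([_hw_microstates(n, f, rng) for f in freqs])
    n_causal = int(round(fraction_causal * m_snps))
    causal_idx = rng.choice(m_snps, size=n_causal, replace=False)
    arch = np.array(["null"] * m_snps, dtype=object)
    for j, idx in enumerate(sorted(causal_idx)):
        arch[idx] = architectures[j % len(architectures)]
    y = rng.normal(0.0, noise_sd, n)
    if np.any(arch == "sign_flip"):
        s = rng.choice((-1.0, 1.0), size=n)
        y = y + s * subpop_half_gap
    for idx in np.flatnonzero(arch == "linear"):
        y = y + effect_size * microstates[idx]
    for idx in np.flatnonzero(arch == "sign_flip"):
        y = y + s * effect_size * microstates[idx]
    snp_specs = []
    truth_rows = []
    for j in range(m_snps):
        chrom = str(1 + j % n_chromosomes)
        pos = 10_000 * (1 + j // n_chromosomes)
        snp_id = f"snp{j:04d}"
        snp_specs.append((snp_id, chrom, pos))
        a_true = effect_size if arch[j] != "null" else 0.0
        truth_rows.append((snp_id, arch[j], a_true, 0.0))
    return _cohort(snp_specs, microstates, y, truth_rows, seed)
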