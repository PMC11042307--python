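"""Conventional single-marker quantities for comparison with the path statistic.

Group means per microstate, Falconer gene effect a = (mu+ - mu-)/2 and
dominance d = mu0 - (mu+ + mu-)/2, two-group t-tests, an OLS dosage
regression as a plain GWAS stand-in, fixed-effect residual adjustment,
PLINK-style SNP QC (MAF, missingness, Hardy-Weinberg exact test) and greedy
LD pruning with Bonferroni thresholds on the independent-SNP count.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import GenotypeMatrix, MicrostateVector, encode_matrix


@dataclass
class MarkerEffects:
    mu_plus: float
    mu_zero: float
    mu_minus: float
    n_plus: int
    n_zero: int
    n_minus: int
    a: float  # NaN when a homozygote group is empty
    d: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.a) or math.isnan(self.d))


def group_means(residuals, v: MicrostateVector):
    """(mu+, mu0, mu-) of residuals per microstate group; NaN for empty groups."""
    residuals = np.asarray(residuals, dtype=float)
    vals = v.values
    out = []
    for target in (1.0, 0.0, -1.0):
        sel = vals == target
        out.append(float(residuals[sel].mean()) if sel.any() else float("nan"))
    return tuple(out)


def gene_effect_dominance(mu_plus, mu_zero, mu_minus, convention: str = "falconer"):
    """Gene effect a and dominance d from the three group means.

    ``falconer``: a = (mu+ - mu-)/2, d = mu0 - (mu+ + mu-)/2 (heterozygote
    displacement from the homozygote midpoint). ``a_minus_mu0``: d = a - mu0,
    an alternative literal reading of the same footnote, kept behind this
    switch. Undefined (NaN) when either homozygote mean is missing.
    """
    if math.isnan(mu_plus) or math.isnan(mu_minus):
        return float("nan"), float("nan")
    a = (mu_plus - mu_minus) / 2.0
    if math.isnan(mu_zero):
        return a, float("nan")
    if convention == "falconer":
        d = mu_zero - (mu_plus + mu_minus) / 2.0
    elif convention == "a_minus_mu0":
        d = a - mu_zero
    else:
        raise ValueError(f"unknown dominance convention {convention!r}")
    return a, d


def marker_effects(residuals, v: MicrostateVector, convention="falconer") -> MarkerEffects:
    mu_plus, mu_zero, mu_minus = group_means(residuals, v)
    n_plus, n_zero, n_minus, _ = v.counts
    a, d = gene_effect_dominance(mu_plus, mu_zero, mu_minus, convention)
    return MarkerEffects(mu_plus, mu_zero, mu_minus, n_plus, n_zero, n_minus, a, d)


def two_group_ttest(x, y, welch: bool = False):
    """Two-sided Student t-test of group means (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def ols_marker_test(residuals, v: MicrostateVector):
    """OLS of residual on microstate dosage (-1/0/+1): (beta, se, p).

    A deliberately plain single-marker baseline (no kinship correction).
    Returns NaNs for monomorphic vectors.
    """
    residuals = np.asarray(residuals, dtype=float)
    mask = v.mask
    y = residuals[mask]
    x = v.values[mask]
    if len(y) < 3 or np.all(x == x[0]):
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def fixed_effects_adjust(y, factors: pd.DataFrame, log_transform: bool = False):
    """Residuals of y after removing categorical main effects by least squares.

    Fits mean + one-hot main effects (rank-deficient designs handled by
    the least-squares solver, so collinear factors are harmless). With
    ``log_transform`` the natural log is applied to y first. Idempotent:
    adjusting the returned residuals again is a no-op.
    """
    y = np.asarray(y, dtype=float)
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive phenotypes")
        y = np.log(y)
    if factors is None or factors.shape[1] == 0:
        return y - y.mean()
    factors = pd.DataFrame(factors)
    if len(factors) != len(y):
        raise ValueError(f"{len(y)} phenotypes vs {len(factors)} factor rows")
    for col in factors.columns:
        counts = factors[col].value_counts()
        singletons = counts[counts == 1]
        if len(singletons):
            warnings.warn(
                f"factor {col!r} has single-observation levels: "
                f"{list(singletons.index)}"
            )
    dummies = pd.get_dummies(factors.astype(str), drop_first=False, dtype=float)
    design = np.column_stack([np.ones(len(y)), dummies.to_numpy()])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


# ---------------------------------------------------------------------------
# SNP quality control


def hwe_exact_test(n_het: int, n_hom_1: int, n_hom_2: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities <= observed).

    Full enumeration of heterozygote counts conditional on the allele
    counts, with the conditional probability recurrence
    P(h+2)/P(h) = hom1(h) * hom2(h) * 4 / ((h+2)(h+1)) evaluated in a
    numerically stable normalized pass.
    """
    if min(n_het, n_hom_1, n_hom_2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom_1 + n_hom_2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_1, n_hom_2) + n_het  # rare-allele copies
    # enumerate possible het counts with the same parity as `rare`
    h0 = rare % 2
    probs = {}
    h = h0
    cur = 1.0
    probs[h] = cur
    while h + 2 <= min(rare, 2 * n - rare):
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        cur = cur * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        probs[h] = cur
    total = sum(probs.values())
    p_obs = probs.get(n_het)
    if p_obs is None:
        raise ValueError("heterozygote count inconsistent with allele counts")
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)) / total)


def _allele_stats(rec):
    """Allele counts, het count and hom counts of a biallelic SNP record."""
    allele_counts = Counter()
    n_het = 0
    n_called = 0
    for call in rec.calls:
        if call is None:
            continue
        a, b = call
        allele_counts[a] += 1
        allele_counts[b] += 1
        n_called += 1
        if a != b:
            n_het += 1
    return allele_counts, n_het, n_called


def snp_filters(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    hwe_p_min: float = 1e-6,
):
    """PLINK-style QC: drop SNPs by MAF, missingness and HWE exact test.

    Returns (kept snp_id list, per-SNP QC DataFrame with drop reasons).
    MAF and HWE use called genotypes only (pairwise deletion). Idempotent.
    """
    rows = []
    kept = []
    n_ind = gm.n_individuals
    for rec in gm.snps:
        allele_counts, n_het, n_called = _allele_stats(rec)
        missing_rate = 1.0 - n_called / n_ind if n_ind else 1.0
        if n_called == 0:
            rows.append((rec.snp_id, 0.0, missing_rate, float("nan"), "all_missing"))
            continue
        if len(allele_counts) > 2:
            rows.append(
                (rec.snp_id, float("nan"), missing_rate, float("nan"), "multiallelic")
            )
            continue
        freqs = sorted(allele_counts.values())
        maf = freqs[0] / (2 * n_called) if len(freqs) == 2 else 0.0
        if len(allele_counts) == 2:
            alleles = sorted(allele_counts)
            n_hom_a = sum(
                1 for c in rec.calls if c is not None and c[0] == c[1] == alleles[0]
            )
            n_hom_b = n_called - n_het - n_hom_a
            hwe_p = hwe_exact_test(n_het, n_hom_a, n_hom_b)
        else:
            hwe_p = 1.0
        reason = ""
        if missing_rate > max_missing:
            reason = "missingness"
        elif maf < maf_min:
            reason = "maf"
        elif hwe_p < hwe_p_min:
            reason = "hwe"
        rows.append((rec.snp_id, maf, missing_rate, hwe_p, reason))
        if not reason:
            kept.append(rec.snp_id)
    qc = pd.DataFrame(
        rows, columns=["snp_id", "maf", "missing_rate", "hwe_p", "dropped_reason"]
    )
    return kept, qc


def ld_prune(gm: GenotypeMatrix, r2_threshold: float = 0.1):
    """Greedy positional LD pruning on microstate dosages, per chromosome.

    Scans SNPs in input order within each chromosome; a SNP is kept unless
    its squared Pearson correlation with any previously kept SNP on the
    same chromosome exceeds the threshold. Zero-variance SNPs never block
    others and are themselves kept (they carry no LD information).
    """
    vectors = {v.snp_id: v.values for v in encode_matrix(gm)}
    kept = []
    by_chrom = {}
    for rec in gm.snps:
        x = vectors[rec.snp_id]
        keep = True
        for other_id in by_chrom.get(rec.chromosome, []):
            y = vectors[other_id]
            both = ~np.isnan(x) & ~np.isnan(y)
            if both.sum() < 3:
                continue
            xs, ys = x[both], y[both]
            if xs.std() == 0 or ys.std() == 0:
                continue
            r = np.corrcoef(xs, ys)[0, 1]
            if r * r > r2_threshold:
                keep = False
                break
        if keep:
            kept.append(rec.snp_id)
            by_chrom.setdefault(rec.chromosome, []).append(rec.snp_id)
    return kept


def bonferroni_threshold(n_independent: int, level: float) -> float:
    """-log10(level / n_independent), the Manhattan-plot dashed line."""
    if n_independent < 1:
        raise ValueError("n_independent must be >= 1")
    return float(-math.log10(level / n_independent))
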