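"""GIFT significance: extremum partition, combinatorial p-value, calibration, FDR.

The anchored difference delta(i) of a genetic path attains a maximum
Phi1 >= 0 and a minimum Phi2 <= 0 over positions 1..N. The first such
positions split the string into three blocks of lengths Di1, Di2, Di3.
With n_q^p microstates of type q in block p, the number of arrangements
consistent with the observed block contents is N1*N2*N3 (a product of
multinomials), out of N0_path = N!/(N+! N0! N-!) arrangements in total,
giving the path probability

    p_hat = N1 * N2 * N3 / N0_path.

p_hat is a score, not a uniform p-value: its null distribution is
estimated by scrambling (theoretic SNPs), pooled into 95%/99% significance
thresholds on -log10 p_hat, and optionally converted to a permutation
empirical p-value before Benjamini-Hochberg adjustment. All counting is
done in log-gamma space (N around 565 overflows any fixed-width integer).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

from .genetic_path import _as_counts, cumulative_path, delta_scaled
from .null_model import permute_strings

_LN10 = math.log(10)


@dataclass
class PathPartition:
    """Extremum positions and the three-block split of one path."""

    i_max: int  # first position of the maximum of delta over 1..N
    i_min: int  # first position of the minimum
    i1: int  # lower boundary = min(i_max, i_min)
    i2: int  # upper boundary = max(i_max, i_min)
    lengths: tuple  # (Di1, Di2, Di3), summing to N
    region_counts: tuple  # ((n+^1,n0^1,n-^1), ..., ...) per block
    phi1: Fraction  # max delta (>= 0)
    phi2: Fraction  # min delta (<= 0)

    @property
    def n(self) -> int:
        return sum(self.lengths)


@dataclass
class GiftPvalue:
    p_hat: float
    mlog10: float  # -log10 p_hat, computed in log space (no underflow)


@dataclass
class SignificanceThresholds:
    """Pooled null quantiles of -log10 p_hat across theoretic SNPs."""

    level95: float
    level99: float
    levels: tuple
    pooled_null_mlog10: np.ndarray
    per_snp_null_mlog10: dict  # counts tuple -> K-vector of null -log10 p_hat
    K: int
    seed: object
    degenerate: bool = False  # e.g. a monomorphic theoretic SNP


def partition_at_extrema(ordered) -> PathPartition:
    """Locate the first max/min of the anchored difference and split the string.

    Extrema are searched over positions 1..N on the exact integer scale
    N*delta(i) (ties -> smallest index). Blocks are the half-open position
    ranges (0,i1], (i1,i2], (i2,N]; the extremum's microstate belongs to the
    block it terminates. A flat path yields i_max = i_min = 1.
    """
    ordered = np.asarray(ordered, dtype=np.int8)
    n = len(ordered)
    if n == 0:
        raise ValueError("empty microstate string")
    counts = (
        int(np.sum(ordered == 1)),
        int(np.sum(ordered == 0)),
        int(np.sum(ordered == -1)),
        n,
    )
    theta = cumulative_path(ordered)
    d = delta_scaled(theta, counts)  # integer N*delta
    interior = d[1:]
    i_max = int(np.argmax(interior)) + 1
    i_min = int(np.argmin(interior)) + 1
    i1, i2 = sorted((i_max, i_min))
    blocks = (ordered[:i1], ordered[i1:i2], ordered[i2:])
    region_counts = tuple(
        (int(np.sum(b == 1)), int(np.sum(b == 0)), int(np.sum(b == -1)))
        for b in blocks
    )
    return PathPartition(
        i_max=i_max,
        i_min=i_min,
        i1=i1,
        i2=i2,
        lengths=(i1, i2 - i1, n - i2),
        region_counts=region_counts,
        phi1=Fraction(int(d[i_max]), n),
        phi2=Fraction(int(d[i_min]), n),
    )


def log_multinomial(length: int, counts) -> float:
    """log of length! / prod(counts!) via log-gamma; exact 0 for length 0."""
    counts = tuple(int(c) for c in counts)
    if any(c < 0 for c in counts) or length < 0:
        raise ValueError(f"negative count in ({length}; {counts})")
    if sum(counts) != length:
        raise ValueError(f"counts {counts} do not sum to length {length}")
    return float(gammaln(length + 1) - sum(gammaln(c + 1) for c in counts))


def gift_raw_pvalue(partition: PathPartition, counts) -> GiftPvalue:
    """p_hat = N1*N2*N3 / N0_path, computed entirely in log space."""
    n_plus, n_zero, n_minus, n = _as_counts(counts)
    if sum(partition.lengths) != n:
        raise ValueError("partition inconsistent with counts")
    log_n0 = log_multinomial(n, (n_plus, n_zero, n_minus))
    log_regions = sum(
        log_multinomial(length, rc)
        for length, rc in zip(partition.lengths, partition.region_counts)
    )
    mlog10 = max(0.0, (log_n0 - log_regions) / _LN10)
    # clamp the linear-scale value away from exact 0 (mlog10 stays exact)
    p_hat = min(1.0, 10.0 ** -min(mlog10, 300.0))
    return GiftPvalue(p_hat=p_hat, mlog10=mlog10)


def path_pvalue(ordered) -> GiftPvalue:
    """Partition + p-value for one ordered microstate string."""
    ordered = np.asarray(ordered, dtype=np.int8)
    part = partition_at_extrema(ordered)
    counts = (
        int(np.sum(ordered == 1)),
        int(np.sum(ordered == 0)),
        int(np.sum(ordered == -1)),
        len(ordered),
    )
    return gift_raw_pvalue(part, counts)


# ---------------------------------------------------------------------------
# exhaustive brute-force oracle (test-scale only)


@dataclass
class OracleResult:
    arrangements: list  # every distinct arrangement (tuples)
    pvalues: list  # exact Fraction p_hat per arrangement

    def cdf(self):
        """Empirical null CDF support: sorted (p, P[p_hat <= p]) pairs."""
        ps = sorted(self.pvalues)
        k = len(ps)
        return [(p, (idx + 1) / k) for idx, p in enumerate(ps)]


def exhaustive_pvalue_oracle(counts, verify: bool = True) -> OracleResult:
    """Enumerate all arrangements of a small multiset and their exact p_hat.

    Independent of the log-gamma pipeline: pure-integer factorials and
    Fractions. When ``verify`` is set, checks for each arrangement that
    N1*N2*N3 equals the enumerated number of arrangements sharing its
    per-block microstate contents. Refuses N > 8.
    """
    import itertools

    n_plus, n_zero, n_minus, n = _as_counts(counts)
    if n > 8:
        raise ValueError(f"N = {n} > 8: exhaustive enumeration refused")
    values = [1] * n_plus + [0] * n_zero + [-1] * n_minus
    arrangements = sorted(set(itertools.permutations(values)))
    f = math.factorial
    n0_path = f(n) // (f(n_plus) * f(n_zero) * f(n_minus))
    assert len(arrangements) == n0_path

    def brute_partition(arr):
        theta = [0]
        for m in arr:
            theta.append(theta[-1] + m)
        dn = n_plus - n_minus
        d = [n * theta[i] - dn * i for i in range(n + 1)]  # integer N*delta
        interior = d[1:]
        i_max = interior.index(max(interior)) + 1
        i_min = interior.index(min(interior)) + 1
        i1, i2 = sorted((i_max, i_min))
        blocks = (arr[:i1], arr[i1:i2], arr[i2:])
        return i1, i2, blocks

    def block_count(block):
        return (block.count(1), block.count(0), block.count(-1))

    pvalues = []
    verified = {}
    for arr in arrangements:
        i1, i2, blocks = brute_partition(arr)
        num = 1
        for block in blocks:
            bp, bz, bm = block_count(block)
            num *= f(len(block)) // (f(bp) * f(bz) * f(bm))
        pvalues.append(Fraction(num, n0_path))
        if verify:
            sig = (i1, i2, tuple(block_count(b) for b in blocks))
            if sig not in verified:
                match = sum(
                    1
                    for other in arrangements
                    if tuple(
                        block_count(b)
                        for b in (other[:i1], other[i1:i2], other[i2:])
                    )
                    == sig[2]
                )
                if match != num:
                    raise AssertionError(
                        f"block-content count {match} != N1*N2*N3 = {num} for {sig}"
                    )
                verified[sig] = match
    return OracleResult(arrangements, pvalues)


# ---------------------------------------------------------------------------
# null calibration and FDR


def mlog10_from_strings(strings) -> np.ndarray:
    """-log10 p_hat for each row of a K x N microstate matrix (vectorized).

    Row-wise equivalent of ``path_pvalue``: extrema of the integer-scaled
    anchored difference located by first-occurrence argmax/argmin, block
    contents read off cumulative per-type counts, multinomials in
    log-gamma space.
    """
    strings = np.asarray(strings, dtype=np.int8)
    if strings.ndim != 2:
        raise ValueError("expected a K x N matrix")
    k, n = strings.shape
    is_plus = strings == 1
    is_zero = strings == 0
    is_minus = strings == -1
    n_plus = is_plus.sum(axis=1)
    n_zero = is_zero.sum(axis=1)
    n_minus = is_minus.sum(axis=1)
    theta = np.cumsum(strings, axis=1, dtype=np.int64)
    pos = np.arange(1, n + 1, dtype=np.int64)
    d = n * theta - (n_plus - n_minus)[:, None] * pos  # N*delta over 1..N
    i_max = np.argmax(d, axis=1) + 1
    i_min = np.argmin(d, axis=1) + 1
    # a flat path must follow the smallest-index tie rule over 1..N;
    # argmax/argmin already return the first occurrence, matching it
    i1 = np.minimum(i_max, i_min)
    i2 = np.maximum(i_max, i_min)
    rows = np.arange(k)
    log_regions = np.zeros(k)
    cum = np.zeros((k, n + 1), dtype=np.int64)
    lengths = (i1, i2 - i1, n - i2)
    bounds_lo = (np.zeros(k, dtype=np.int64), i1, i2)
    bounds_hi = (i1, i2, np.full(k, n, dtype=np.int64))
    total = np.zeros(k)
    for length in lengths:
        log_regions += gammaln(length + 1)
    for mask, n_q in ((is_plus, n_plus), (is_zero, n_zero), (is_minus, n_minus)):
        np.cumsum(mask, axis=1, out=cum[:, 1:])
        cum[:, 0] = 0
        for lo, hi in zip(bounds_lo, bounds_hi):
            log_regions -= gammaln(cum[rows, hi] - cum[rows, lo] + 1)
        total += gammaln(n_q + 1)
    log_n0 = gammaln(n + 1) - total
    return np.maximum(0.0, (log_n0 - log_regions) / _LN10)


def null_mlog10_samples(counts, K: int, rng) -> np.ndarray:
    """-log10 p_hat of K scrambled paths for the given counts."""
    return mlog10_from_strings(permute_strings(counts, K, rng))


def permutation_pvalue(ordered, K: int, rng) -> float:
    """Per-SNP empirical p-value of an observed path against its own null.

    Scrambles the observed string K times and returns
    (1 + #{null -log10 p_hat >= observed}) / (K + 1) -- a valid
    (super-uniform) p-value conditioned on the SNP's microstate counts.
    """
    ordered = np.asarray(ordered, dtype=np.int8)
    obs = path_pvalue(ordered).mlog10
    null = mlog10_from_strings(rng.permuted(np.tile(ordered, (K, 1)), axis=1))
    return float((1 + np.sum(null >= obs)) / (K + 1))


def calibrate_thresholds(
    theoretic_counts, K: int = 1000, seed=None, levels=(0.95, 0.99)
) -> SignificanceThresholds:
    """Pool null -log10 p_hat across theoretic SNPs; thresholds = pooled quantiles.

    ``theoretic_counts`` is an iterable of (N+, N0, N-) or (N+, N0, N-, N)
    tuples. Reproducible for a fixed (counts, K, seed).
    """
    if K < 100:
        warnings.warn(f"K = {K} < 100: threshold quantiles will be unstable")
    counts_list = [_as_counts(c) for c in theoretic_counts]
    if not counts_list:
        raise ValueError("no theoretic SNPs supplied")
    rng = np.random.default_rng(seed)
    per_snp = {}
    degenerate = False
    for counts in counts_list:
        samples = null_mlog10_samples(counts, K, rng)
        per_snp[counts] = samples
        if np.allclose(samples, 0.0):
            degenerate = True  # e.g. monomorphic: p_hat identically 1
    pooled = np.concatenate(list(per_snp.values()))
    qs = np.quantile(pooled, levels)
    return SignificanceThresholds(
        level95=float(np.quantile(pooled, 0.95)),
        level99=float(np.quantile(pooled, 0.99)),
        levels=tuple(zip(levels, qs.tolist())),
        pooled_null_mlog10=pooled,
        per_snp_null_mlog10=per_snp,
        K=K,
        seed=seed,
        degenerate=degenerate,
    )


def empirical_pvalues(obs_mlog10, null_mlog10) -> np.ndarray:
    """Permutation p-value (1 + #{null >= obs}) / (K + 1) per observation.

    Valid (super-uniform) under the null; suitable input for BH, unlike
    raw p_hat whose null distribution concentrates far below 1.
    """
    obs = np.atleast_1d(np.asarray(obs_mlog10, dtype=float))
    null = np.sort(np.asarray(null_mlog10, dtype=float))
    k = len(null)
    # count of null >= obs via searchsorted on the sorted null
    ge = k - np.searchsorted(null, obs, side="left")
    return (1.0 + ge) / (k + 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
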