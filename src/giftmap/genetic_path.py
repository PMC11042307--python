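"""Genetic paths: phenotype-ranked cumulative sums of microstates.

For one SNP, order the N callable individuals by ascending phenotypic
residual and cumulate their microstates: theta(i), i = 0..N, theta(0) = 0.
Absent phenotypic information the expected path is the straight line
theta0(i) = tan(alpha) * i with tan(alpha) = (N+ - N-)/N, so all inference
concentrates on the anchored difference delta(i) = theta(i) - theta0(i),
which is exactly zero at both ends.

The slope is carried as an exact Fraction; ``delta_scaled`` gives the
integer-valued N*delta used for deterministic extremum ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .encoding import DegenerateSnpError, MicrostateVector


@dataclass
class GeneticPath:
    snp_id: str
    ordered: np.ndarray  # length-N int8 microstate string, ascending-residual order
    theta: np.ndarray  # length-(N+1) int64 cumulative sum, theta[0]=0
    slope: Fraction  # tan(alpha) = (N+ - N-)/N
    delta: np.ndarray  # length-(N+1) float, theta[i] - slope*i

    @property
    def n(self) -> int:
        return len(self.ordered)

    @property
    def counts(self):
        n_plus = int(np.sum(self.ordered == 1))
        n_zero = int(np.sum(self.ordered == 0))
        n_minus = int(np.sum(self.ordered == -1))
        return n_plus, n_zero, n_minus, len(self.ordered)


def rank_by_phenotype(residuals, v: MicrostateVector, descending: bool = False):
    """Order microstates by ascending residual; stable input-order tie-break.

    ``residuals`` and ``v`` must cover the same individuals with missing
    genotypes already dropped (no NaN microstates).
    """
    residuals = np.asarray(residuals, dtype=float)
    values = np.asarray(v.values, dtype=float)
    if len(residuals) != len(values):
        raise ValueError(
            f"{v.snp_id}: {len(residuals)} residuals vs {len(values)} microstates"
        )
    if np.any(np.isnan(values)):
        raise ValueError(f"{v.snp_id}: missing microstates must be dropped first")
    if not np.all(np.isfinite(residuals)):
        raise ValueError(f"{v.snp_id}: non-finite residual value")
    key = -residuals if descending else residuals
    order = np.argsort(key, kind="stable")
    return values[order].astype(np.int8)


def cumulative_path(ordered) -> np.ndarray:
    """theta(i) = sum of the first i microstates, anchored at theta(0)=0."""
    ordered = np.asarray(ordered, dtype=np.int64)
    theta = np.empty(len(ordered) + 1, dtype=np.int64)
    theta[0] = 0
    np.cumsum(ordered, out=theta[1:])
    return theta


def null_line_slope(counts) -> Fraction:
    """tan(alpha) = (N+ - N-)/N, the asymptotic permutation-mean slope."""
    n_plus, _, n_minus, n = _as_counts(counts)
    if n == 0:
        raise DegenerateSnpError("N = 0: no callable individuals")
    return Fraction(n_plus - n_minus, n)


def delta_path(theta, slope) -> np.ndarray:
    """delta(i) = theta(i) - slope*i in doubles (for plotting/export)."""
    theta = np.asarray(theta, dtype=float)
    return theta - float(slope) * np.arange(len(theta))


def delta_scaled(theta, counts) -> np.ndarray:
    """Exact integer N*delta(i) = N*theta(i) - (N+ - N-)*i.

    Shares delta's argmax/argmin positions; used for deterministic
    extremum location.
    """
    n_plus, _, n_minus, n = _as_counts(counts)
    theta = np.asarray(theta, dtype=np.int64)
    return n * theta - (n_plus - n_minus) * np.arange(len(theta), dtype=np.int64)


def build_path(residuals, v: MicrostateVector, descending: bool = False) -> GeneticPath:
    """Full per-SNP path construction with pairwise deletion of missing calls."""
    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) != len(v.values):
        raise ValueError(
            f"{v.snp_id}: {len(residuals)} residuals vs {len(v.values)} individuals"
        )
    mask = v.mask
    kept = MicrostateVector(v.snp_id, v.values[mask])
    ordered = rank_by_phenotype(residuals[mask], kept, descending=descending)
    theta = cumulative_path(ordered)
    n_plus, n_zero, n_minus, n = kept.counts
    slope = null_line_slope((n_plus, n_zero, n_minus, n))
    delta = delta_path(theta, slope)
    return GeneticPath(v.snp_id, ordered, theta, slope, delta)


def path_table(path: GeneticPath):
    """Per-position export rows ``position theta delta microstate`` (microstate
    blank at position 0)."""
    import pandas as pd

    n = path.n
    return pd.DataFrame(
        {
            "position": np.arange(n + 1),
            "theta": path.theta,
            "delta": path.delta,
            "microstate": np.concatenate([[np.iinfo(np.int8).min], path.ordered]),
        }
    ).replace(np.iinfo(np.int8).min, np.nan)


def _as_counts(counts):
    """Accept (N+,N0,N-), (N+,N0,N-,N), or a MicrostateVector."""
    if isinstance(counts, MicrostateVector):
        return counts.counts
    counts = tuple(int(c) for c in counts)
    if len(counts) == 3:
        return counts + (sum(counts),)
    if len(counts) == 4:
        if counts[3] != sum(counts[:3]):
            raise ValueError(f"inconsistent counts {counts}")
        return counts
    raise ValueError(f"counts must have 3 or 4 entries, got {counts}")
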