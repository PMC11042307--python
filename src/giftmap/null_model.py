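"""Permutation null ensemble of genetic paths.

Scrambling the microstate string destroys phenotypic ordering; repeating
the scramble yields an ensemble of null paths theta0(i) that all share the
endpoints theta0(0)=0 and theta0(N)=N+ - N-. The per-position variance has
the closed form of a without-replacement partial sum,

    Var theta0(i) = i (N - i) / (N - 1) * sigma2_m,

where sigma2_m is the population variance of the N microstate values. The
normalized spread sd/sqrt(N) against i/N is a sample-size-independent
quadratic-shaped arc, which the simulated ensemble cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_path import _as_counts, cumulative_path, null_line_slope


@dataclass
class NullEnsemble:
    counts: tuple  # (N+, N0, N-, N)
    K: int
    mean_path: np.ndarray  # per-position mean of theta0(i), length N+1
    sd_path: np.ndarray  # per-position sd, length N+1
    seed: object
    p_hat_samples: np.ndarray | None = None  # filled by significance.calibrate

    @property
    def normalized_sd(self) -> np.ndarray:
        """sigma(i/N) = sd_path / sqrt(N), the plotted size-free spread."""
        return self.sd_path / np.sqrt(self.counts[3])


def base_vector(counts) -> np.ndarray:
    """Canonical unshuffled microstate vector: N+ ones, N0 zeros, N- minus-ones."""
    n_plus, n_zero, n_minus, _ = _as_counts(counts)
    return np.concatenate(
        [
            np.ones(n_plus, dtype=np.int8),
            np.zeros(n_zero, dtype=np.int8),
            -np.ones(n_minus, dtype=np.int8),
        ]
    )


def permute_string(counts_or_values, rng) -> np.ndarray:
    """One uniformly random arrangement of the microstate multiset."""
    if isinstance(counts_or_values, np.ndarray):
        return rng.permutation(counts_or_values)
    return rng.permutation(base_vector(counts_or_values))


def permute_path(counts_or_values, rng) -> np.ndarray:
    """One null path realization theta0(i), i = 0..N."""
    return cumulative_path(permute_string(counts_or_values, rng))


def permute_strings(counts, K, rng) -> np.ndarray:
    """K x N matrix of independent random arrangements (row-wise shuffles)."""
    base = base_vector(counts)
    return rng.permuted(np.tile(base, (K, 1)), axis=1)


def simulate_null_ensemble(counts, K: int = 1000, seed=None, rng=None) -> NullEnsemble:
    """Mean/sd summaries of K scrambled paths for the given counts."""
    if K < 1:
        raise ValueError("K must be >= 1")
    counts = _as_counts(counts)
    if rng is None:
        rng = np.random.default_rng(seed)
    strings = permute_strings(counts, K, rng)
    n = counts[3]
    theta = np.zeros((K, n + 1), dtype=np.int64)
    np.cumsum(strings, axis=1, out=theta[:, 1:])
    mean_path = theta.mean(axis=0)
    sd_path = theta.std(axis=0, ddof=1) if K > 1 else np.zeros(n + 1)
    return NullEnsemble(counts, K, mean_path, sd_path, seed)


def microstate_population_variance(counts) -> float:
    """sigma2_m: variance of the N microstate values as a finite population."""
    n_plus, _, n_minus, n = _as_counts(counts)
    if n == 0:
        raise ValueError("N = 0")
    mean = (n_plus - n_minus) / n
    return (n_plus + n_minus) / n - mean**2


def null_variance_closed_form(counts, i) -> float:
    """Var theta0(i) = i(N-i)/(N-1) * sigma2_m; 0 when N = 1.

    ``i`` may be a scalar or array of positions in [0, N].
    """
    counts = _as_counts(counts)
    n = counts[3]
    i = np.asarray(i)
    if np.any(i < 0) or np.any(i > n):
        raise ValueError(f"position out of range [0, {n}]")
    if n == 1:
        return np.zeros_like(i, dtype=float) if i.ndim else 0.0
    var = i * (n - i) / (n - 1) * microstate_population_variance(counts)
    return var if var.ndim else float(var)


def ensemble_table(ens: NullEnsemble):
    """Export rows ``position mean sd`` for envelope plots."""
    import pandas as pd

    return pd.DataFrame(
        {
            "position": np.arange(ens.counts[3] + 1),
            "mean": ens.mean_path,
            "sd": ens.sd_path,
        }
    )


def mean_line(counts) -> np.ndarray:
    """The asymptotic mean path tan(alpha)*i at every position."""
    counts = _as_counts(counts)
    return float(null_line_slope(counts)) * np.arange(counts[3] + 1)
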