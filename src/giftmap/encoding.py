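"""Genotype-call encoding into microstates.

A bi-allelic diploid genotype at one SNP is collapsed to a single integer
*microstate*: +1 for A/A or T/T homozygotes, -1 for G/G or C/C homozygotes,
and 0 for every other non-missing allele pair (heterozygotes, and the
homozygote-ambiguous A/T and G/C pairs). Missing calls propagate as missing
and are dropped per SNP (pairwise deletion) downstream -- they are never
imputed to 0, which would distort path shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGT")

#: sentinel for a missing call in the genotype TSV dialect
MISSING_CALL = "NN"


class InvalidAlleleError(ValueError):
    """An allele letter outside {A, C, G, T} was encountered."""


class DegenerateSnpError(ValueError):
    """A SNP with no callable individuals (N = 0)."""


@dataclass
class SnpRecord:
    """One SNP's identity and per-individual allele-pair calls.

    ``calls[k]`` is a 2-tuple of base letters for individual ``k`` or
    ``None`` when missing. ``chromosome`` is an opaque label; the phantom
    label "0" (unplaced SNPs) is legal.
    """

    snp_id: str
    chromosome: str
    position: int
    calls: list

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"{self.snp_id}: negative position {self.position}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs collection of allele-pair calls."""

    individual_ids: list
    snps: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.individual_ids)
        for rec in self.snps:
            if len(rec.calls) != n:
                raise ValueError(
                    f"SNP {rec.snp_id}: {len(rec.calls)} calls for {n} individuals"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class MicrostateVector:
    """Encoded microstates for one SNP.

    ``values`` is a float array aligned to the individual order, holding
    +1.0 / 0.0 / -1.0 and NaN for missing calls.
    """

    snp_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if not np.all(np.isin(finite, (-1.0, 0.0, 1.0))):
            raise ValueError(f"{self.snp_id}: microstate values outside {{+1,0,-1}}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of non-missing individuals."""
        return ~np.isnan(self.values)

    def non_missing(self) -> np.ndarray:
        """Microstates of callable individuals, input order, as int8."""
        return self.values[self.mask].astype(np.int8)

    @property
    def counts(self):
        return microstate_counts(self)

    @property
    def n(self) -> int:
        return int(self.mask.sum())


def encode_genotype(call, *, snp_id=None, individual=None):
    """Encode one allele pair to a microstate integer (or None if missing).

    +1 if both alleles are A or both are T; -1 if both are G or both are C;
    0 for any other non-missing pair. Allele order is irrelevant.
    """
    if call is None:
        return None
    a, b = call
    for allele in (a, b):
        if allele not in VALID_BASES:
            where = ""
            if snp_id is not None or individual is not None:
                where = f" (SNP {snp_id!r}, individual {individual!r})"
            raise InvalidAlleleError(f"invalid allele {allele!r}{where}")
    if a == b:
        return 1 if a in "AT" else -1
    return 0


def encode_matrix(gm: GenotypeMatrix):
    """Encode every SNP of a genotype matrix; returns list of MicrostateVector."""
    out = []
    for rec in gm.snps:
        vals = np.full(len(rec.calls), np.nan)
        for k, call in enumerate(rec.calls):
            m = encode_genotype(
                call, snp_id=rec.snp_id, individual=gm.individual_ids[k]
            )
            if m is not None:
                vals[k] = m
        out.append(MicrostateVector(rec.snp_id, vals))
    return out


def microstate_counts(v: MicrostateVector):
    """Tallies (N+, N0, N-, N) of the non-missing microstates."""
    vals = v.values
    n_plus = int(np.sum(vals == 1.0))
    n_zero = int(np.sum(vals == 0.0))
    n_minus = int(np.sum(vals == -1.0))
    return n_plus, n_zero, n_minus, n_plus + n_zero + n_minus
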