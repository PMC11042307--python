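"""Readers, writers, run configuration and the end-to-end pipeline.

Genotype input formats:

* **tsv** -- the package's own dialect: header ``id <snp1> <snp2> ...``;
  cells are two-letter strings ("AA", "AG", ...) or "NN" for missing. SNP
  metadata (chromosome, position) may be supplied in a sidecar ``.map``
  file or defaults to the phantom chromosome "0".
* **vcf** -- diploid GT fields resolved to REF/ALT base letters (cyvcf2);
  half-calls and missing GT become missing.
* **ped** -- PLINK .ped with companion .map; "0 0" is missing.

``run_gift`` is a pure function of (inputs, config): encode -> QC -> rank
-> path -> partition -> p_hat -> thresholds/BH, plus the OLS baseline,
writing one results row per SNP. Per-SNP randomness is derived from the
master seed and a stable hash of the SNP id, so results are independent
of SNP order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects_baseline as eb
from . import significance as sig
from .encoding import MISSING_CALL, GenotypeMatrix, SnpRecord, encode_matrix
from .genetic_path import build_path
from .synthetic_data import THEORETIC_PRESETS


@dataclass
class RunConfig:
    """Everything a run depends on; serialized into every output header."""

    genotype_path: str = ""
    genotype_format: str = "tsv"  # tsv | vcf | ped
    phenotype_path: str = ""
    phenotype_column: str = "phenotype"
    fixed_effect_columns: tuple = ()
    log_transform: bool = False
    apply_qc: bool = True
    maf_min: float = 0.05
    max_missing: float = 0.10
    hwe_p_min: float = 1e-6
    theoretic_counts: tuple = tuple(THEORETIC_PRESETS.values())
    calibration_K: int = 1000
    empirical_K: int = 999  # per-SNP permutation replicates for p_emp
    levels: tuple = (0.95, 0.99)
    bh_level: float = 0.05
    dominance_convention: str = "falconer"
    descending: bool = False
    seed: int = 0
    out_dir: str = "."

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["theoretic_counts"] = [list(c) for c in self.theoretic_counts]
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["theoretic_counts"] = tuple(tuple(c) for c in d["theoretic_counts"])
        for key in ("fixed_effect_columns", "levels"):
            d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def snp_seed(master_seed: int, snp_id: str) -> int:
    """Stable per-SNP seed below 2^31, independent of SNP order."""
    return (int(master_seed) * 2654435761 + zlib.crc32(snp_id.encode())) % (2**31)


# ---------------------------------------------------------------------------
# genotype readers / writers


def read_genotypes(path, fmt: str = "tsv", map_path=None) -> GenotypeMatrix:
    if fmt == "tsv":
        return read_genotype_tsv(path, map_path=map_path)
    if fmt == "vcf":
        return read_genotype_vcf(path)
    if fmt == "ped":
        return read_genotype_ped(path, map_path=map_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _parse_cell(cell, snp_id, line_no):
    if cell == MISSING_CALL:
        return None
    if len(cell) != 2:
        raise ValueError(f"line {line_no}: malformed call {cell!r} for SNP {snp_id}")
    return (cell[0], cell[1])


def read_genotype_tsv(path, map_path=None) -> GenotypeMatrix:
    """Read the package TSV dialect (individuals as rows, SNPs as columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: first header column must be 'id'")
        snp_ids = header[1:]
        ids = []
        columns = [[] for _ in snp_ids]
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path} line {line_no}: {len(parts)} fields, expected {len(header)}"
                )
            ids.append(parts[0])
            for j, cell in enumerate(parts[1:]):
                columns[j].append(_parse_cell(cell, snp_ids[j], line_no))
    meta = _read_map(map_path) if map_path else {}
    snps = [
        SnpRecord(sid, *meta.get(sid, ("0", 0)), calls)
        for sid, calls in zip(snp_ids, columns)
    ]
    return GenotypeMatrix(ids, snps)


def write_genotype_tsv(gm: GenotypeMatrix, path):
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + [rec.snp_id for rec in gm.snps]) + "\n")
        for k, ind in enumerate(gm.individual_ids):
            cells = [
                MISSING_CALL if rec.calls[k] is None else "".join(rec.calls[k])
                for rec in gm.snps
            ]
            fh.write("\t".join([ind] + cells) + "\n")


def _read_map(path):
    """PLINK-style .map: chrom, snp_id, (cM,) position -> {snp_id: (chrom, pos)}."""
    meta = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, sid, _, pos = parts
            elif len(parts) == 3:
                chrom, sid, pos = parts
            else:
                raise ValueError(f"{path} line {line_no}: expected 3 or 4 fields")
            meta[sid] = (chrom, int(pos))
    return meta


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Diploid GT indices resolved to REF/ALT letters; half-calls -> missing."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snps = []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        calls = []
        for gt in var.genotypes:  # [allele1, allele2, phased]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                calls.append(None)
            else:
                calls.append((alleles[a], alleles[b]))
        snp_id = var.ID if var.ID else f"{var.CHROM}_{var.POS}"
        snps.append(SnpRecord(snp_id, str(var.CHROM), int(var.POS), calls))
    vcf.close()
    return GenotypeMatrix(ids, snps)


def read_genotype_ped(path, map_path=None) -> GenotypeMatrix:
    """PLINK .ped (allele-pair columns) with companion .map for SNP metadata."""
    path = Path(path)
    if map_path is None:
        map_path = path.with_suffix(".map")
    order = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                order.append((parts[1], parts[0], int(parts[-1])))
    ids = []
    snp_calls = [[] for _ in order]
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(order):
                raise ValueError(
                    f"{path} line {line_no}: {len(parts)} fields for "
                    f"{len(order)} mapped SNPs"
                )
            ids.append(parts[1])  # within-family individual id
            for j in range(len(order)):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                snp_calls[j].append(None if a == "0" or b == "0" else (a, b))
    snps = [
        SnpRecord(sid, chrom, pos, calls)
        for (sid, chrom, pos), calls in zip(order, snp_calls)
    ]
    return GenotypeMatrix(ids, snps)


def read_phenotypes(path, id_column: str = "id") -> pd.DataFrame:
    """Phenotype/factor TSV keyed by individual id; duplicate ids are fatal."""
    df = pd.read_csv(path, sep="\t", dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r}")
    if df[id_column].duplicated().any():
        dupes = df[id_column][df[id_column].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate ids {dupes}")
    return df.set_index(id_column)


def write_phenotype_tsv(ids, phenotype, path, column="phenotype"):
    pd.DataFrame({"id": ids, column: phenotype}).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class GiftRunResult:
    results: pd.DataFrame
    thresholds: sig.SignificanceThresholds
    qc: pd.DataFrame | None
    config: RunConfig
    log: list = field(default_factory=list)


def align_phenotypes(gm: GenotypeMatrix, pheno: pd.DataFrame, config: RunConfig):
    """Match phenotype rows to genotype individuals; adjust fixed effects."""
    common = [i for i in gm.individual_ids if i in pheno.index]
    if not common:
        raise ValueError("no overlapping individuals between genotypes and phenotypes")
    pheno = pheno.loc[common]
    y = pheno[config.phenotype_column].to_numpy(dtype=float)
    factors = (
        pheno[list(config.fixed_effect_columns)]
        if config.fixed_effect_columns
        else None
    )
    residuals = eb.fixed_effects_adjust(y, factors, log_transform=config.log_transform)
    keep = np.array([i in pheno.index for i in gm.individual_ids])
    gm_sub = GenotypeMatrix(
        common,
        [
            SnpRecord(
                r.snp_id,
                r.chromosome,
                r.position,
                [c for c, k in zip(r.calls, keep) if k],
            )
            for r in gm.snps
        ],
    )
    return gm_sub, residuals


def run_gift(
    gm: GenotypeMatrix,
    residuals,
    config: RunConfig | None = None,
    thresholds: sig.SignificanceThresholds | None = None,
) -> GiftRunResult:
    """Full per-SNP pipeline on already-adjusted residuals."""
    config = config or RunConfig()
    residuals = np.asarray(residuals, dtype=float)
    log = [f"snps_read={gm.n_snps}", f"individuals={gm.n_individuals}"]
    qc = None
    if config.apply_qc:
        kept_ids, qc = eb.snp_filters(
            gm, config.maf_min, config.max_missing, config.hwe_p_min
        )
        kept = set(kept_ids)
        gm = GenotypeMatrix(
            gm.individual_ids, [r for r in gm.snps if r.snp_id in kept]
        )
        log.append(f"snps_after_qc={gm.n_snps}")
    if thresholds is None:
        thresholds = sig.calibrate_thresholds(
            config.theoretic_counts,
            K=config.calibration_K,
            seed=snp_seed(config.seed, "__calibration__"),
            levels=config.levels,
        )
    vectors = encode_matrix(gm)
    rows = []
    for rec, v in zip(gm.snps, vectors):
        n_plus, n_zero, n_minus, n = v.counts
        flags = []
        if n == 0:
            continue
        monomorphic = (n_plus == n) or (n_zero == n) or (n_minus == n)
        if monomorphic:
            flags.append("monomorphic")
        path = build_path(residuals, v, descending=config.descending)
        part = sig.partition_at_extrema(path.ordered)
        pv = sig.gift_raw_pvalue(part, path.counts)
        # per-SNP permutation p-value, conditioned on this SNP's counts
        p_emp = sig.permutation_pvalue(
            path.ordered,
            config.empirical_K,
            np.random.default_rng(snp_seed(config.seed, rec.snp_id)),
        )
        eff = eb.marker_effects(residuals, v, convention=config.dominance_convention)
        if not eff.defined:
            flags.append("undefined_a_d")
        beta, se, p_gwas = eb.ols_marker_test(residuals, v)
        rows.append(
            {
                "chrom": rec.chromosome,
                "snp": rec.snp_id,
                "pos": rec.position,
                "N+": n_plus,
                "N0": n_zero,
                "N-": n_minus,
                "p_hat": pv.p_hat,
                "mlog10_p_hat": pv.mlog10,
                "p_emp": p_emp,
                "a": eff.a,
                "d": eff.d,
                "beta_gwas": beta,
                "p_gwas": p_gwas,
                "flags": ";".join(flags),
            }
        )
    results = pd.DataFrame(rows)
    if len(results):
        results["p_gift"] = sig.bh_adjust(results["p_hat"].to_numpy())
        results["mlog10_p_gift"] = -np.log10(results["p_gift"])
        results["p_emp_bh"] = sig.bh_adjust(results["p_emp"].to_numpy())
        results["mlog10_p_gwas"] = -np.log10(results["p_gwas"])
        results["significant_95"] = results["mlog10_p_hat"] > thresholds.level95
        results["significant_99"] = results["mlog10_p_hat"] > thresholds.level99
        results = results[
            [
                "chrom",
                "snp",
                "pos",
                "N+",
                "N0",
                "N-",
                "p_hat",
                "mlog10_p_hat",
                "p_gift",
                "mlog10_p_gift",
                "p_emp",
                "p_emp_bh",
                "a",
                "d",
                "beta_gwas",
                "p_gwas",
                "mlog10_p_gwas",
                "significant_95",
                "significant_99",
                "flags",
            ]
        ]
    log.append(f"snps_tested={len(results)}")
    return GiftRunResult(results, thresholds, qc, config, log)


def run_gift_files(config: RunConfig) -> GiftRunResult:
    """File-based entry point: read, align, run, write outputs."""
    gm = read_genotypes(config.genotype_path, config.genotype_format)
    pheno = read_phenotypes(config.phenotype_path)
    gm, residuals = align_phenotypes(gm, pheno, config)
    run = run_gift(gm, residuals, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(run, out / "results.tsv")
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {
                "config_hash": config.config_hash,
                "seed": config.seed,
                "level95": run.thresholds.level95,
                "level99": run.thresholds.level99,
                "K": run.thresholds.K,
            },
            fh,
            indent=2,
        )
    return run


def write_results(run: GiftRunResult, path):
    """Results TSV with a provenance header line."""
    with open(path, "w") as fh:
        fh.write(f"# giftmap config_hash={run.config.config_hash} seed={run.config.seed}\n")
        run.results.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_comparison(results: pd.DataFrame, truth: pd.DataFrame | None = None, top_k: int = 100):
    """Rank GIFT against the OLS baseline; top-k overlap and quadrants.

    Returns (per-SNP table with rank/quadrant columns, summary dict).
    Quadrants follow the scatter of the two -log10 p's thresholded at each
    method's top-k cutoff: Q2 = both, Q1 = baseline only, Q4 = GIFT only.
    """
    df = results.copy()
    df["rank_gift"] = df["mlog10_p_hat"].rank(ascending=False, method="first")
    df["rank_gwas"] = df["mlog10_p_gwas"].rank(ascending=False, method="first")
    top_gift = df["rank_gift"] <= top_k
    top_gwas = df["rank_gwas"] <= top_k
    df["quadrant"] = np.select(
        [top_gift & top_gwas, top_gwas & ~top_gift, top_gift & ~top_gwas],
        ["Q2", "Q1", "Q4"],
        default="Q3",
    )
    if truth is not None:
        df = df.merge(
            truth.rename(columns={"snp_id": "snp"}), on="snp", how="left"
        )
    summary = {
        "top_k": top_k,
        "overlap": int((top_gift & top_gwas).sum()),
        "gift_only": int((top_gift & ~top_gwas).sum()),
        "gwas_only": int((top_gwas & ~top_gift).sum()),
    }
    return df, summary
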