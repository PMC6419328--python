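"""End-to-end pipeline driver: simulate -> QC -> PCA -> TOH -> cTOH ->
association -> integration, with every intermediate written to disk and a
run log that reconciles counts across stages.

Two runs with the same configuration produce byte-identical tabular outputs
(the run log additionally carries wall-clock timestamps).
"""

from __future__ import annotations

import datetime as _dt
import os
import tomllib
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from . import io as tio
from .association import associate_all
from .core import ConfigurationError
from .ctoh import assign_carriers, define_ctohs, regions_table, toh_coverage
from .integration import cluster_indels, ir_summary, recurrent_indels, shortlist_genes
from .popstruct import covariate_matrix
from .qc import QCThresholds, apply_qc
from .synthetic import (
    ExomeConfig,
    PlantedTract,
    SimConfig,
    simulate_cohort,
    simulate_exome_features,
)
from .toh import TOHParams, call_tohs_matrix


@dataclass
class PipelineConfig:
    """All stage parameters in one place.

    ``seed`` drives both simulators (their own seeds are overridden so a
    single integer reproduces the whole run).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    exome: ExomeConfig = field(default_factory=ExomeConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    toh: TOHParams = field(default_factory=TOHParams)
    n_pcs: int = 2
    min_subjects: int = 10
    min_snps: int = 100
    min_cover_frac: float = 0.9
    fdr_threshold: float = 0.05
    min_samples: int = 3
    merge_window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 0:
            raise ConfigurationError("n_pcs must be >= 0")
        if self.min_subjects < 1 or self.min_snps < 1:
            raise ConfigurationError("min_subjects and min_snps must be >= 1")
        if not 0.0 < self.min_cover_frac <= 1.0:
            raise ConfigurationError("min_cover_frac must lie in (0, 1]")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ConfigurationError("fdr_threshold must lie in (0, 1]")
        if self.min_samples < 1:
            raise ConfigurationError("min_samples must be >= 1")
        if self.merge_window < 0:
            raise ConfigurationError("merge_window must be >= 0")


_SECTION_TYPES = {
    "sim": SimConfig,
    "exome": ExomeConfig,
    "qc": QCThresholds,
    "toh": TOHParams,
}


def load_config(path: str) -> PipelineConfig:
    """Read a flat TOML configuration; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs: dict = {}
    top_fields = {f.name for f in dc_fields(PipelineConfig)}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            valid = {f.name for f in dc_fields(cls)}
            unknown = set(value) - valid
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in [{key}]: {sorted(unknown)}"
                )
            if key == "sim" and "planted_tracts" in value:
                value = dict(value)
                value["planted_tracts"] = tuple(
                    PlantedTract(**t) for t in value["planted_tracts"]
                )
            if key == "sim" and "maf_range" in value:
                value = dict(value)
                value["maf_range"] = tuple(value["maf_range"])
            kwargs[key] = cls(**value)
        elif key in top_fields:
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")
    return PipelineConfig(**kwargs)


def default_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale demonstration config: 100 cases / 100 controls across
    4 chromosomes x 2,000 SNPs with three planted tracts (one strongly
    over-represented in cases, one moderate, one null)."""
    tracts = (
        PlantedTract("chr1", 400, 150, p_case=0.45, p_control=0.05),
        PlantedTract("chr2", 900, 140, p_case=0.30, p_control=0.10),
        PlantedTract("chr3", 600, 130, p_case=0.20, p_control=0.20),
    )
    return PipelineConfig(
        sim=SimConfig(planted_tracts=tracts, seed=seed),
        exome=ExomeConfig(seed=seed),
        seed=seed,
    )


class RunLog:
    """Stage-by-stage record with count reconciliation."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, stage: str, **counts) -> None:
        self.records.append(
            {
                "time": _dt.datetime.now().isoformat(timespec="seconds"),
                "stage": stage,
                **counts,
            }
        )

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                extras = " ".join(
                    f"{k}={v}" for k, v in rec.items() if k not in ("time", "stage")
                )
                fh.write(f"{rec['time']}\t{rec['stage']}\t{extras}\n")


def run_all(config: PipelineConfig, out_dir: str) -> RunLog:
    """Execute the full synthetic-cohort pipeline into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    log = RunLog()

    def path(name: str) -> str:
        return os.path.join(out_dir, name)

    # simulate ------------------------------------------------------------
    sim_cfg = SimConfig(**{**_as_dict(config.sim), "seed": config.seed})
    cohort = simulate_cohort(sim_cfg)
    gm = cohort.genotypes
    tio.write_plink(gm, path("cohort.ped"), path("cohort.map"))
    tio.write_phenotypes(gm, path("phenotypes.tsv"))
    truth_rows = []
    for tract, carrier in cohort.truth_tracts:
        lo_bp, hi_bp = cohort.tract_bp_span(tract)
        truth_rows.append(
            {
                "chrom": tract.chrom,
                "start_snp_index": tract.start_snp_index,
                "n_snps": tract.n_snps,
                "p_case": tract.p_case,
                "p_control": tract.p_control,
                "start_bp": lo_bp,
                "end_bp": hi_bp,
                "n_carriers": int(carrier.sum()),
            }
        )
    tio.write_tsv(pd.DataFrame(truth_rows), path("truth_tracts.tsv"))
    log.add("simulate", n_samples=gm.n_samples, n_snps=gm.n_snps, seed=config.seed)

    # qc ------------------------------------------------------------------
    gm_qc, report = apply_qc(gm, config.qc)
    tio.write_tsv(report.snp_stats, path("qc_snp_stats.tsv"))
    tio.write_tsv(report.samples_removed, path("qc_samples_removed.tsv"))
    tio.write_tsv(report.snps_removed, path("qc_snps_removed.tsv"))
    tio.write_plink(gm_qc, path("qc.ped"), path("qc.map"))
    log.add(
        "qc",
        samples_in=report.n_samples_in,
        samples_removed=len(report.samples_removed),
        samples_kept=report.n_samples_kept,
        snps_in=report.n_snps_in,
        snps_removed=len(report.snps_removed),
        snps_kept=report.n_snps_kept,
    )

    # toh -----------------------------------------------------------------
    tohs = call_tohs_matrix(gm_qc, config.toh)
    toh_df = pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "start0": t.start_bp - 1,
                "end": t.end_bp,
                "sample_id": t.sample_id,
                "n_snps": t.n_snps,
                "start_idx": t.start,
                "end_idx": t.end,
            }
            for t in tohs
        ],
        columns=["chrom", "start0", "end", "sample_id", "n_snps", "start_idx", "end_idx"],
    )
    tio.write_tsv(toh_df, path("toh_calls.tsv"))
    log.add("toh", n_calls=len(tohs))

    # ctoh ----------------------------------------------------------------
    coverage = toh_coverage(tohs, gm_qc.markers)
    regions = define_ctohs(
        coverage, gm_qc.markers, config.min_subjects, config.min_snps
    )
    tio.write_tsv(regions_table(regions), path("ctoh_regions.tsv"))
    tio.write_bed([r.interval() for r in regions], path("ctoh_regions.bed"))
    carriers = assign_carriers(
        regions,
        tohs,
        list(gm_qc.samples["sample_id"]),
        config.min_cover_frac,
    )
    tio.write_tsv(carriers, path("carriers.tsv"), index=True)
    log.add("ctoh", n_regions=len(regions))

    # pca (excluding cTOH-region markers, so stratification axes are not
    # driven by the shared-homozygosity signal under test) ----------------
    exclude = np.concatenate(
        [np.arange(r.start, r.end + 1) for r in regions]
    ) if regions else np.empty(0, dtype=int)
    covar = covariate_matrix(gm_qc, k=config.n_pcs, exclude_snps=exclude)
    tio.write_tsv(covar, path("covariates.tsv"))
    log.add("pca", k=config.n_pcs, n_markers_excluded=len(exclude))

    # association ---------------------------------------------------------
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = associate_all(
            regions,
            carriers,
            gm_qc.samples["phenotype"].to_numpy(),
            covar,
        )
    tio.write_tsv(results, path("association.tsv"))
    sig = results[(results["fdr_q"] < config.fdr_threshold)].copy()
    log.add("association", n_tested=int(results["converged"].sum()), n_significant=len(sig))

    # integration ---------------------------------------------------------
    sig_ivs = [
        r.interval() for r in regions if r.region_id in set(sig["region_id"])
    ]
    exome_cfg = ExomeConfig(
        **{
            **_as_dict(config.exome),
            "seed": config.seed,
            "min_samples": config.min_samples,
            "n_planted": config.exome.n_planted if sig_ivs else 0,
        }
    )
    exome = simulate_exome_features(exome_cfg, sig_ivs)
    tio.write_bed(exome.repeats, path("repeats.bed"))
    tio.write_genes_bed(exome.genes, path("genes.bed"))
    tio.write_indels_tsv(exome.indels, path("indels.tsv"))
    tio.write_indel_vcf(exome.indels, path("indels.vcf"))
    tio.write_tsv(
        pd.DataFrame({"gene": exome.truth_shortlist}), path("truth_shortlist.tsv")
    )

    clusters = cluster_indels(exome.indels, config.merge_window)
    retained = recurrent_indels(clusters, exome.repeats, config.min_samples)
    shortlist = shortlist_genes(exome.genes, sig_ivs, retained, exome.repeats)
    tio.write_tsv(
        pd.DataFrame(
            [
                {
                    "gene": e.gene.symbol,
                    "chrom": e.gene.chrom,
                    "start": e.gene.start,
                    "end": e.gene.end,
                    "region_id": e.region_id,
                    "n_samples": len(e.samples),
                    "samples": ",".join(e.samples),
                    "n_repeats": len(e.repeats),
                }
                for e in shortlist
            ],
            columns=[
                "gene",
                "chrom",
                "start",
                "end",
                "region_id",
                "n_samples",
                "samples",
                "n_repeats",
            ],
        ),
        path("shortlist.tsv"),
    )
    tio.write_tsv(
        ir_summary(exome.repeats, sig_ivs, exome.genes), path("ir_summary.tsv")
    )
    log.add(
        "integrate",
        n_clusters=len(clusters),
        n_retained=len(retained),
        n_shortlisted=len(shortlist),
    )

    log.write(path("runlog.txt"))
    return log


def _as_dict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dc_fields(obj)}
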