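"""Synthetic cohorts and exome annotation sets with recorded ground truth.

The cohort generator emulates a dense biallelic SNP-array panel
(Human610-Quad scale spacing, ~5 kb between markers): per-SNP allele
frequencies drawn from a configurable MAF band, genotypes in Hardy-Weinberg
proportions, optional two-subpopulation structure under the Balding-Nichols
model, independent per-call dropout, and homozygous tracts planted at chosen
case/control carrier probabilities.  Tract carriers are overwritten with the
locally major allele at every tract SNP, so carriers share identical
homozygous calls and contain no heterozygous or missing call inside the span.

The exome generator produces per-sample indel calls (lengths 1-191 bp),
inverted/simple repeat intervals (log-uniform lengths, 39-21,947 bp, mean of
the log-uniform law ~4.4 kb) and gene models, planting at least one gene that
satisfies the downstream integration filter so the full pipeline can be
validated against recorded truth.

Everything is deterministic given the config seed; each stage draws from its
own child stream of a single ``SeedSequence`` so adding a stage never
perturbs the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import HOM_A, HOM_B, MISSING, ConfigurationError, GenotypeMatrix
from .integration import GeneModel, GenomicInterval, IndelCall


@dataclass(frozen=True)
class PlantedTract:
    """Ground-truth homozygous tract planted into the cohort.

    ``p_case`` / ``p_control`` are the carrier probabilities in each group;
    the tract covers ``n_snps`` consecutive markers starting at 0-based
    ``start_snp_index`` on its chromosome.
    """

    chrom: str
    start_snp_index: int
    n_snps: int
    p_case: float
    p_control: float

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("planted tract needs n_snps >= 1")
        if self.start_snp_index < 0:
            raise ConfigurationError("planted tract start index must be >= 0")
        for p in (self.p_case, self.p_control):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("carrier probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters.

    ``fst`` > 0 splits the cohort into two subpopulations whose per-SNP
    allele frequencies are drawn Balding-Nichols:
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``.
    ``sex_ratio`` is the probability of being male (sex code 1).
    """

    n_cases: int = 100
    n_controls: int = 100
    n_chromosomes: int = 4
    snps_per_chr: int = 2000
    bp_spacing_mean: float = 5000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.0
    planted_tracts: tuple[PlantedTract, ...] = ()
    sex_ratio: float = 0.5
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("need at least one case and one control")
        if self.n_chromosomes <= 0:
            raise ConfigurationError("n_chromosomes must be positive")
        if self.snps_per_chr < 0:
            raise ConfigurationError("snps_per_chr must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError("fst must lie in [0, 1)")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        object.__setattr__(self, "planted_tracts", tuple(self.planted_tracts))
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for t in self.planted_tracts:
            if t.chrom not in chroms:
                raise ConfigurationError(
                    f"planted tract on unknown chromosome {t.chrom}"
                )
            if t.start_snp_index + t.n_snps > self.snps_per_chr:
                raise ConfigurationError(
                    f"planted tract {t.chrom}:{t.start_snp_index}+{t.n_snps} "
                    "does not fit on its chromosome"
                )

    @property
    def n_individuals(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    truth_tracts: list[tuple[PlantedTract, np.ndarray]]
    covariate_truth: np.ndarray  # subpopulation label (0/1) per individual

    def tract_bp_span(self, tract: PlantedTract) -> tuple[int, int]:
        """bp span [first SNP bp, last SNP bp] of a planted tract."""
        markers = self.genotypes.markers
        on_chrom = markers.index[markers["chrom"] == tract.chrom]
        first = int(markers.loc[on_chrom[tract.start_snp_index], "bp"])
        last = int(
            markers.loc[on_chrom[tract.start_snp_index + tract.n_snps - 1], "bp"]
        )
        return first, last


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw a cohort under the configured model; deterministic given seed."""
    (
        rng_map,
        rng_freq,
        rng_pop,
        rng_geno,
        rng_miss,
        rng_sex,
        rng_tract,
    ) = _streams(config.seed, 7)

    n = config.n_individuals
    m_total = config.n_chromosomes * config.snps_per_chr

    # marker map: exponential spacing, cumulative 1-based bp
    chrom_col: list[str] = []
    bp_col: list[int] = []
    for chrom in config.chromosomes:
        gaps = rng_map.exponential(config.bp_spacing_mean, size=config.snps_per_chr)
        gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
        bp = np.cumsum(gaps)
        chrom_col.extend([chrom] * config.snps_per_chr)
        bp_col.extend(bp.tolist())
    markers = pd.DataFrame(
        {
            "chrom": chrom_col,
            "snp_id": [f"snp_{i + 1:07d}" for i in range(m_total)],
            "bp": bp_col,
        }
    )

    # ancestral allele-B frequencies
    p = rng_freq.uniform(config.maf_range[0], config.maf_range[1], size=m_total)

    # subpopulation structure
    if config.fst > 0.0:
        subpop = rng_pop.integers(0, 2, size=n)
        f = config.fst
        p_sub = np.empty((2, m_total))
        for s in (0, 1):
            p_sub[s] = rng_pop.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
        p_ind = p_sub[subpop]
    else:
        subpop = np.zeros(n, dtype=int)
        p_ind = np.broadcast_to(p, (n, m_total))

    # HWE genotypes as allele-B dosage 0/1/2 (== HOM_A/HET/HOM_B codes)
    calls = rng_geno.binomial(2, p_ind).astype(np.int8) if m_total else np.zeros(
        (n, 0), dtype=np.int8
    )

    # independent per-call dropout
    if config.missing_rate > 0.0 and m_total:
        calls[rng_miss.random((n, m_total)) < config.missing_rate] = MISSING

    # sample table: cases first, then controls
    phenotype = np.r_[np.ones(config.n_cases, int), np.zeros(config.n_controls, int)]
    sex = (rng_sex.random(n) < config.sex_ratio).astype(int)
    samples = pd.DataFrame(
        {
            "sample_id": [f"case_{i + 1:04d}" for i in range(config.n_cases)]
            + [f"control_{i + 1:04d}" for i in range(config.n_controls)],
            "sex": sex,
            "phenotype": phenotype,
        }
    )

    # planted tracts overwrite carriers with the locally major allele,
    # applied after dropout so tract spans contain no missing call
    chrom_offset = {
        chrom: i * config.snps_per_chr for i, chrom in enumerate(config.chromosomes)
    }
    truth: list[tuple[PlantedTract, np.ndarray]] = []
    for tract in config.planted_tracts:
        u = rng_tract.random(n)
        carrier = np.where(phenotype == 1, u < tract.p_case, u < tract.p_control)
        lo = chrom_offset[tract.chrom] + tract.start_snp_index
        span = slice(lo, lo + tract.n_snps)
        major = np.where(p[span] > 0.5, HOM_B, HOM_A).astype(np.int8)
        calls[np.ix_(np.flatnonzero(carrier), np.arange(span.start, span.stop))] = major
        truth.append((tract, carrier))

    gm = GenotypeMatrix(calls=calls, samples=samples, markers=markers)
    return SyntheticCohort(genotypes=gm, truth_tracts=truth, covariate_truth=subpop)


def implied_odds_ratio(p_case: float, p_control: float) -> float:
    """Population odds ratio implied by the two carrier probabilities."""
    for p in (p_case, p_control):
        if not 0.0 < p < 1.0:
            raise ConfigurationError(
                "implied odds ratio undefined at boundary probabilities"
            )
    return (p_case * (1.0 - p_control)) / (p_control * (1.0 - p_case))


# ---------------------------------------------------------------------------
# exome feature simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExomeConfig:
    """Parameters for the exome-derived annotation simulator.

    Indel lengths are uniform on ``indel_length_range`` (1-191 bp, the span
    exome indel calls realistically take); repeat lengths are log-uniform on
    ``repeat_length_range`` (39-21,947 bp).  ``n_samples`` defaults to the
    eight-exome validation-series design.  Decoy genes exercise each failure
    mode of the integration filter (too few samples, no repeat overlap,
    outside every significant region).
    """

    n_samples: int = 8
    indel_length_range: tuple[int, int] = (1, 191)
    repeat_length_range: tuple[int, int] = (39, 21947)
    n_genes: int = 24
    gene_length_range: tuple[int, int] = (5_000, 100_000)
    n_background_repeats: int = 150
    n_background_indels: int = 120
    n_planted: int = 1
    include_decoys: bool = True
    min_samples: int = 3
    jitter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ConfigurationError("n_samples must be >= 0")
        lo, hi = self.indel_length_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("bad indel_length_range")
        lo, hi = self.repeat_length_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("bad repeat_length_range")
        if self.n_planted > 0 and self.min_samples > max(self.n_samples, 0):
            raise ConfigurationError(
                "cannot plant a recurrent cluster: min_samples exceeds n_samples"
            )


@dataclass
class SyntheticExomeSet:
    repeats: list[GenomicInterval]
    indels: list[IndelCall]
    genes: list[GeneModel]
    truth_shortlist: list[str]


def _random_repeat(rng, chrom: str, pos: int, cfg: ExomeConfig, label: str) -> GenomicInterval:
    lo, hi = cfg.repeat_length_range
    length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    length = min(max(length, lo), hi)
    start = max(0, pos - length // 2)
    cls = "inverted" if rng.random() < 0.5 else "simple"
    return GenomicInterval(chrom, start, start + length, cls, label)


def simulate_exome_features(
    config: ExomeConfig,
    ctoh_regions: Sequence[GenomicInterval],
    chrom_sizes: dict[str, int] | None = None,
) -> SyntheticExomeSet:
    """Generate repeats, per-sample indels and genes around cTOH regions.

    At least one planted gene (``GENE_TRUTH_*``) satisfies the full
    integration filter: an indel cluster recurring in >= ``min_samples``
    samples, overlapping a repeat, inside a cTOH region.  Background indels
    are placed clear of the cTOH regions so that, with decoys excluded by
    design, the downstream shortlist equals ``truth_shortlist`` exactly.
    """
    regions = list(ctoh_regions)
    if config.n_planted > 0 and not regions:
        raise ConfigurationError("cannot plant shortlist genes without cTOH regions")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    sample_ids = [f"exome_{i + 1}" for i in range(config.n_samples)]

    if chrom_sizes is None:
        chrom_sizes = {}
        for r in regions:
            chrom_sizes[r.chrom] = max(
                chrom_sizes.get(r.chrom, 0), int(r.end * 1.5) + 2_000_000
            )
        if not chrom_sizes:
            chrom_sizes = {"chr1": 10_000_000}

    chroms = sorted(chrom_sizes)
    region_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        region_by_chrom.setdefault(r.chrom, []).append(r)

    def in_any_region(chrom: str, start: int, end: int) -> bool:
        return any(
            start < r.end and r.start < end for r in region_by_chrom.get(chrom, ())
        )

    genes: list[GeneModel] = []
    repeats: list[GenomicInterval] = []
    indels: list[IndelCall] = []
    truth: list[str] = []
    forbidden: list[GenomicInterval] = []  # spans background repeats must avoid

    glo, ghi = config.gene_length_range

    def place_gene(symbol: str, chrom: str, anchor: int, size: int) -> GeneModel:
        start = max(0, anchor - size // 2)
        gene = GeneModel(symbol, chrom, start, start + size)
        genes.append(gene)
        return gene

    def plant_cluster(
        gene: GeneModel, n_samples: int, members: Sequence[str], with_repeat: bool
    ) -> None:
        site = int(rng.integers(gene.start + 50, gene.end - 250))
        if with_repeat:
            repeats.append(
                _random_repeat(rng, gene.chrom, site, config, f"rep_{gene.symbol}")
            )
        else:
            forbidden.append(GenomicInterval(gene.chrom, gene.start, gene.end))
        for s in members:
            jitter = int(rng.integers(0, config.jitter + 1))
            length = int(rng.integers(*_incl(config.indel_length_range)))
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            indels.append(IndelCall(s, gene.chrom, site + jitter, length, kind))

    # --- planted truth genes ------------------------------------------------
    if config.n_samples > 0:
        for i in range(config.n_planted):
            region = regions[i % len(regions)]
            mid = (region.start + region.end) // 2
            size = min(ghi, max(glo, region.length // 2))
            gene = place_gene(f"GENE_TRUTH_{i + 1}", region.chrom, mid, size)
            members = list(
                rng.choice(sample_ids, size=config.min_samples, replace=False)
            )
            plant_cluster(gene, config.min_samples, members, with_repeat=True)
            truth.append(gene.symbol)

        # --- decoys ---------------------------------------------------------
        if config.include_decoys and regions:
            # (a) recurrence failure: cluster in min_samples-1 samples
            region = regions[0]
            anchor = region.start + region.length // 4
            gene = place_gene(
                "GENE_DECOY_FEWSAMPLES", region.chrom, anchor, max(glo, 20_000)
            )
            k = max(1, config.min_samples - 1)
            members = list(rng.choice(sample_ids, size=min(k, config.n_samples), replace=False))
            plant_cluster(gene, k, members, with_repeat=True)

            # (b) repeat failure: recurrent cluster but no repeat anywhere near
            region = regions[-1]
            anchor = region.start + 3 * region.length // 4
            gene = place_gene(
                "GENE_DECOY_NOREPEAT", region.chrom, anchor, max(glo, 20_000)
            )
            members = list(
                rng.choice(sample_ids, size=config.min_samples, replace=False)
            )
            plant_cluster(gene, config.min_samples, members, with_repeat=False)

            # (c) spatial failure: everything present but outside every region
            chrom = chroms[0]
            anchor = chrom_sizes[chrom] - max(glo, 20_000) * 2
            while in_any_region(chrom, anchor - ghi, anchor + ghi):
                anchor -= ghi
            gene = place_gene("GENE_DECOY_OUTSIDE", chrom, anchor, max(glo, 20_000))
            members = list(
                rng.choice(sample_ids, size=config.min_samples, replace=False)
            )
            plant_cluster(gene, config.min_samples, members, with_repeat=True)

    # --- background genes ---------------------------------------------------
    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        size = int(rng.integers(glo, ghi + 1))
        anchor = int(rng.integers(size, max(size + 1, chrom_sizes[chrom] - size)))
        place_gene(f"GENE{i + 1:04d}", chrom, anchor, size)

    # --- background repeats, clear of no-repeat decoy spans -----------------
    tries = 0
    placed = 0
    while placed < config.n_background_repeats and tries < 50 * config.n_background_repeats:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, chrom_sizes[chrom]))
        rep = _random_repeat(rng, chrom, pos, config, f"rep_bg_{placed + 1}")
        if any(rep.overlaps(f) for f in forbidden):
            continue
        repeats.append(rep)
        placed += 1

    # --- background indels, outside every cTOH region -----------------------
    if config.n_samples > 0:
        placed = 0
        tries = 0
        lo, hi = config.indel_length_range
        while placed < config.n_background_indels and tries < 50 * config.n_background_indels:
            tries += 1
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(0, chrom_sizes[chrom]))
            length = int(rng.integers(lo, hi + 1))
            if in_any_region(chrom, pos - 1000, pos + length + 1000):
                continue
            sample = sample_ids[int(rng.integers(config.n_samples))]
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            indels.append(IndelCall(sample, chrom, pos, length, kind))
            placed += 1

    genes.sort(key=lambda g: (g.chrom, g.start, g.symbol))
    repeats.sort()
    indels.sort()
    return SyntheticExomeSet(
        repeats=repeats, indels=indels, genes=genes, truth_shortlist=sorted(truth)
    )


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1
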