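"""Genotype quality control.

Filters mirror routine SNP-array QC: sample genotype call rate, per-SNP
missingness, an exact Hardy-Weinberg equilibrium test, and a minor-allele
frequency floor.  Samples are filtered first so that all per-SNP statistics
are computed on the retained individuals; the SNP filters are then applied in
the fixed order missingness -> HWE -> MAF, and the first failing filter is
recorded as the removal reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, DataError, GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the four routine filters.

    Defaults: samples need a >= 95% genotype call rate; SNPs are dropped for
    missingness > 5%, an exact HWE p-value below 1e-7, or MAF below 0.03.
    """

    min_sample_call_rate: float = 0.95
    max_snp_missingness: float = 0.05
    hwe_alpha: float = 1e-7
    min_maf: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "min_sample_call_rate",
            "max_snp_missingness",
            "hwe_alpha",
            "min_maf",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Record of what QC removed and the statistics behind each decision.

    ``notes`` lists checks that are part of routine array QC but have no
    algorithmic definition here (non-random genotyping failure, pipetting
    contamination); they are recorded as not assessed.
    """

    samples_removed: pd.DataFrame
    snps_removed: pd.DataFrame
    sample_call_rates: pd.DataFrame
    snp_stats: pd.DataFrame
    n_samples_in: int
    n_snps_in: int
    notes: tuple[str, ...] = (
        "non-random genotyping failure: not assessed",
        "contamination from pipetting errors: not assessed",
    )

    @property
    def n_samples_kept(self) -> int:
        return self.n_samples_in - len(self.samples_removed)

    @property
    def n_snps_kept(self) -> int:
        return self.n_snps_in - len(self.snps_removed)


def sample_call_rate(genotype_row: np.ndarray) -> float:
    """Fraction of non-missing calls in one individual's genotype row."""
    row = np.asarray(genotype_row)
    if row.size == 0:
        raise DataError("cannot compute call rate of an empty genotype row")
    return float((row != MISSING).sum() / row.size)


def minor_allele_frequency(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """MAF from genotype counts: ``min(fA, fB)`` over the two allele
    frequencies at a biallelic SNP."""
    total = n_hom_a + n_het + n_hom_b
    if total <= 0:
        raise DataError("MAF undefined for zero genotyped individuals")
    f_a = (2 * n_hom_a + n_het) / (2 * total)
    f_b = (2 * n_hom_b + n_het) / (2 * total)
    return float(min(f_a, f_b))


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and enumerates every
    heterozygote count compatible with them; each configuration's probability
    under the HWE null is obtained by a stable mode-anchored recurrence, and
    the p-value is the summed probability of all configurations no more
    probable than the observed one (two-sided, probability-ordered).

    Returns 1.0 for monomorphic SNPs (a single possible configuration).
    """
    a, b, c = int(n_hom_a), int(n_het), int(n_hom_b)
    if min(a, b, c) < 0:
        raise DataError("negative genotype count")
    n = a + b + c
    if n == 0:
        raise DataError("HWE test undefined for zero individuals")
    n_a = 2 * a + b
    n_b = 2 * c + b
    na = min(n_a, n_b)  # minor allele count
    nb = max(n_a, n_b)
    if na == 0:
        return 1.0

    # Heterozygote counts share the parity of the minor allele count.
    h_min = na % 2
    h_max = na
    # anchor the recurrence at the (approximate) modal het count
    mode = int(round(na * nb / (2.0 * n)))
    if mode % 2 != h_min % 2:
        mode += 1
    mode = min(max(mode, h_min), h_max)

    n_values = (h_max - h_min) // 2 + 1
    probs = np.empty(n_values, dtype=float)

    def idx(h: int) -> int:
        return (h - h_min) // 2

    probs[idx(mode)] = 1.0
    # upward: P(h+2)/P(h) = 4*nAA*nBB / ((h+1)(h+2)) with nAA=(na-h)/2 etc.
    h = mode
    while h + 2 <= h_max:
        n_aa = (na - h) // 2
        n_bb = (nb - h) // 2
        probs[idx(h + 2)] = probs[idx(h)] * (4.0 * n_aa * n_bb) / ((h + 1.0) * (h + 2.0))
        h += 2
    # downward: P(h-2)/P(h) = h(h-1) / (4*(nAA+1)(nBB+1))
    h = mode
    while h - 2 >= h_min:
        n_aa = (na - h) // 2
        n_bb = (nb - h) // 2
        probs[idx(h - 2)] = probs[idx(h)] * (h * (h - 1.0)) / (
            4.0 * (n_aa + 1.0) * (n_bb + 1.0)
        )
        h -= 2

    total = probs.sum()
    p_obs = probs[idx(b)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum() / total
    return float(min(p, 1.0))


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the sample filter, then the SNP filters, returning the retained
    matrix and a full report.

    Raises
    ------
    DataError
        If the matrix is empty or the call-rate filter removes every sample.
    """
    thr = thresholds or QCThresholds()
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise DataError("cannot QC an empty genotype matrix")

    # 1. sample call rate, computed on all SNPs as genotyped
    rates = (genotypes.calls != MISSING).mean(axis=1)
    sample_ids = genotypes.samples["sample_id"].to_numpy()
    keep_samples = rates >= thr.min_sample_call_rate
    if not keep_samples.any():
        raise DataError("sample call-rate filter removed every sample")
    samples_removed = pd.DataFrame(
        {
            "sample_id": sample_ids[~keep_samples],
            "reason": "call_rate",
            "call_rate": rates[~keep_samples],
        }
    )
    retained = genotypes.subset(sample_idx=np.flatnonzero(keep_samples))

    # 2. per-SNP statistics on retained samples
    counts = retained.genotype_counts()
    n_called = (
        counts["n_hom_a"] + counts["n_het"] + counts["n_hom_b"]
    ).to_numpy()
    n_retained = retained.n_samples
    missingness = counts["n_missing"].to_numpy() / n_retained
    maf = np.full(retained.n_snps, np.nan)
    hwe_p = np.full(retained.n_snps, np.nan)
    ca = counts["n_hom_a"].to_numpy()
    ch = counts["n_het"].to_numpy()
    cb = counts["n_hom_b"].to_numpy()
    for j in range(retained.n_snps):
        if n_called[j] > 0:
            maf[j] = minor_allele_frequency(ca[j], ch[j], cb[j])
            hwe_p[j] = hwe_exact_test(ca[j], ch[j], cb[j])

    reasons = np.array([""] * retained.n_snps, dtype=object)
    fail_miss = missingness > thr.max_snp_missingness
    fail_hwe = ~fail_miss & (n_called > 0) & (hwe_p < thr.hwe_alpha)
    fail_maf = (
        ~fail_miss & ~fail_hwe & ((n_called == 0) | (maf < thr.min_maf))
    )
    reasons[fail_miss] = "missingness"
    reasons[fail_hwe] = "hwe"
    reasons[fail_maf] = "maf"
    drop = fail_miss | fail_hwe | fail_maf

    snp_ids = retained.markers["snp_id"].to_numpy()
    snp_stats = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "missingness": missingness,
            "maf": maf,
            "hwe_p": hwe_p,
        }
    )
    snps_removed = pd.DataFrame(
        {"snp_id": snp_ids[drop], "reason": reasons[drop]}
    )
    out = retained.subset(snp_idx=np.flatnonzero(~drop))
    report = QCReport(
        samples_removed=samples_removed,
        snps_removed=snps_removed,
        sample_call_rates=pd.DataFrame(
            {"sample_id": sample_ids, "call_rate": rates}
        ),
        snp_stats=snp_stats,
        n_samples_in=genotypes.n_samples,
        n_snps_in=genotypes.n_snps,
    )
    return out, report
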