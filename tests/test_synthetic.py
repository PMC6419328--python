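"""Cohort and exome simulators: reproducibility, planted truth, calibration."""

import numpy as np
import pytest

from tohscan.core import HET, MISSING, ConfigurationError
from tohscan.integration import GenomicInterval
from tohscan.qc import hwe_exact_test
from tohscan.synthetic import (
    ExomeConfig,
    PlantedTract,
    SimConfig,
    implied_odds_ratio,
    simulate_cohort,
    simulate_exome_features,
)

REGIONS = [
    GenomicInterval("chr1", 1_000_000, 1_800_000, "ctoh", "ctoh_0001"),
    GenomicInterval("chr2", 4_000_000, 4_700_000, "ctoh", "ctoh_0002"),
]


def test_zero_snps_gives_empty_matrix():
    cohort = simulate_cohort(SimConfig(snps_per_chr=0, seed=1))
    assert cohort.genotypes.calls.shape == (200, 0)


def test_het_frequency_matches_hwe_expectation():
    # p = 0.3 at every SNP: het fraction ~ Binomial(n, 2pq)/n, 4-sigma band
    cfg = SimConfig(
        n_cases=1000,
        n_controls=1000,
        n_chromosomes=1,
        snps_per_chr=5,
        maf_range=(0.3, 0.3),
        missing_rate=0.0,
        seed=7,
    )
    calls = simulate_cohort(cfg).genotypes.calls
    n = calls.shape[0]
    expect = 2 * 0.3 * 0.7
    sd = np.sqrt(expect * (1 - expect) / n)
    het_frac = (calls == HET).mean(axis=0)
    assert np.all(np.abs(het_frac - expect) < 4 * sd)


def test_planted_tract_forces_homozygous_calls():
    tract = PlantedTract("chr1", 50, 150, p_case=1.0, p_control=0.0)
    cfg = SimConfig(n_chromosomes=1, snps_per_chr=300, planted_tracts=(tract,), seed=3)
    cohort = simulate_cohort(cfg)
    calls = cohort.genotypes.calls
    pheno = cohort.genotypes.samples["phenotype"].to_numpy()
    span = calls[:, 50:200]
    case_span = span[pheno == 1]
    assert not np.any(case_span == HET)
    assert not np.any(case_span == MISSING)
    # all carriers share identical homozygous calls at every tract SNP
    assert np.all(case_span == case_span[0])
    _tract, carrier = cohort.truth_tracts[0]
    assert carrier[pheno == 1].all() and not carrier[pheno == 0].any()


def test_reproducibility_bit_identical():
    cfg = SimConfig(
        n_cases=30,
        n_controls=30,
        snps_per_chr=200,
        fst=0.05,
        planted_tracts=(PlantedTract("chr1", 10, 50, 0.4, 0.1),),
        seed=11,
    )
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
    assert a.genotypes.markers.equals(b.genotypes.markers)
    assert np.array_equal(a.truth_tracts[0][1], b.truth_tracts[0][1])
    assert np.array_equal(a.covariate_truth, b.covariate_truth)


def test_carrier_fraction_within_binomial_band():
    tract = PlantedTract("chr1", 0, 100, p_case=0.3, p_control=0.1)
    cfg = SimConfig(
        n_cases=400, n_controls=400, n_chromosomes=1, snps_per_chr=200,
        planted_tracts=(tract,), seed=5,
    )
    cohort = simulate_cohort(cfg)
    _t, carrier = cohort.truth_tracts[0]
    pheno = cohort.genotypes.samples["phenotype"].to_numpy()
    for p, grp in ((0.3, 1), (0.1, 0)):
        k = carrier[pheno == grp].sum()
        n = (pheno == grp).sum()
        assert abs(k - n * p) < 4 * np.sqrt(n * p * (1 - p))


def test_hwe_calibration_without_structure():
    # fst = 0, no tracts: nearly every SNP passes the exact HWE test at 1e-3
    cfg = SimConfig(
        n_cases=250, n_controls=250, n_chromosomes=1, snps_per_chr=2000,
        missing_rate=0.0, seed=9,
    )
    counts = simulate_cohort(cfg).genotypes.genotype_counts()
    p = np.array(
        [
            hwe_exact_test(a, h, b)
            for a, h, b in zip(counts["n_hom_a"], counts["n_het"], counts["n_hom_b"])
        ]
    )
    assert (p > 1e-3).mean() >= 0.99


def test_tract_must_fit_chromosome():
    with pytest.raises(ConfigurationError):
        SimConfig(
            snps_per_chr=100,
            planted_tracts=(PlantedTract("chr1", 50, 100, 0.5, 0.5),),
        )
    with pytest.raises(ConfigurationError):
        SimConfig(planted_tracts=(PlantedTract("chr99", 0, 10, 0.5, 0.5),))


@pytest.mark.parametrize(
    "p_case,p_control,expected",
    [
        (0.2, 0.2, 1.0),
        (0.3, 0.1, (0.3 * 0.9) / (0.1 * 0.7)),
    ],
)
def test_implied_odds_ratio_values(p_case, p_control, expected):
    assert implied_odds_ratio(p_case, p_control) == pytest.approx(expected, rel=1e-12)


def test_implied_odds_ratio_symmetry_and_bounds():
    assert implied_odds_ratio(0.1, 0.3) == pytest.approx(
        1.0 / implied_odds_ratio(0.3, 0.1), rel=1e-12
    )
    with pytest.raises(ConfigurationError):
        implied_odds_ratio(0.0, 0.5)
    with pytest.raises(ConfigurationError):
        implied_odds_ratio(0.5, 1.0)


def test_exome_lengths_within_configured_bounds():
    cfg = ExomeConfig(n_background_indels=10_000, n_background_repeats=400, seed=2)
    exome = simulate_exome_features(cfg, REGIONS)
    lengths = np.array([c.length for c in exome.indels])
    assert lengths.min() >= 1 and lengths.max() <= 191
    rep_lengths = np.array([r.length for r in exome.repeats])
    assert rep_lengths.min() >= 39 and rep_lengths.max() <= 21_947
    assert exome.truth_shortlist  # at least one planted gene recorded


def test_exome_empty_and_error_cases():
    empty = simulate_exome_features(
        ExomeConfig(n_samples=0, n_planted=0, include_decoys=False, seed=1), REGIONS
    )
    assert empty.indels == []
    with pytest.raises(ConfigurationError):
        simulate_exome_features(ExomeConfig(seed=1), [])
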