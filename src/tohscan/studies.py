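"""Replicated simulation studies: planted-tract recovery and null calibration.

These drive the full analysis path (simulate -> QC -> PCA -> TOH -> cTOH ->
carrier association) many times with fresh seeds and summarize how often the
planted signal is recovered, how well the Wald interval covers the implied
odds ratio, and how calibrated the per-region p-values are under the null.
The default study design is 100 cases + 100 controls on 4 chromosomes x
2,000 SNPs, a planted 150-SNP tract at carrier probabilities 0.30 (cases) /
0.10 (controls) — implied odds ratio 3.857 — and, for the null study, eight
equal-frequency tracts with the phenotype labels permuted.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import kstest

from .association import associate_all
from .ctoh import assign_carriers, define_ctohs, toh_coverage
from .popstruct import covariate_matrix
from .qc import QCThresholds, apply_qc
from .synthetic import PlantedTract, SimConfig, implied_odds_ratio, simulate_cohort
from .toh import TOHParams, call_tohs_matrix

RECOVERY_TRACT = PlantedTract("chr2", 900, 150, p_case=0.30, p_control=0.10)

NULL_TRACTS = tuple(
    PlantedTract(chrom, start, n, p_case=0.25, p_control=0.25)
    for chrom, start, n in [
        ("chr1", 200, 140),
        ("chr1", 1500, 130),
        ("chr2", 300, 150),
        ("chr2", 1400, 120),
        ("chr3", 250, 135),
        ("chr3", 1600, 145),
        ("chr4", 400, 125),
        ("chr4", 1300, 150),
    ]
)


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 so they remain plain C ints everywhere
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def run_case_control_replicate(
    sim_cfg: SimConfig,
    min_subjects: int = 10,
    min_snps: int = 100,
    min_cover_frac: float = 0.9,
    n_pcs: int = 2,
    toh_params: TOHParams | None = None,
    qc_thresholds: QCThresholds | None = None,
    permute_phenotype: bool = False,
    permute_seed: int = 0,
):
    """One full pass of the case-control analysis on a simulated cohort.

    Returns ``(cohort, regions, results)`` where ``results`` is the
    association table over detected cTOH regions.
    """
    cohort = simulate_cohort(sim_cfg)
    gm, _report = apply_qc(cohort.genotypes, qc_thresholds or QCThresholds())
    tohs = call_tohs_matrix(gm, toh_params or TOHParams())
    coverage = toh_coverage(tohs, gm.markers)
    regions = define_ctohs(coverage, gm.markers, min_subjects, min_snps)
    carriers = assign_carriers(
        regions, tohs, list(gm.samples["sample_id"]), min_cover_frac
    )
    exclude = (
        np.concatenate([np.arange(r.start, r.end + 1) for r in regions])
        if regions
        else np.empty(0, dtype=int)
    )
    covar = covariate_matrix(gm, k=n_pcs, exclude_snps=exclude)
    phenotype = gm.samples["phenotype"].to_numpy().copy()
    if permute_phenotype:
        rng = np.random.default_rng(permute_seed)
        phenotype = rng.permutation(phenotype)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = associate_all(regions, carriers, phenotype, covar)
    return cohort, regions, results


def recovery_study(n_replicates: int = 200, seed: int = 0) -> dict:
    """Planted-tract recovery and odds-ratio CI coverage over replicates.

    For each replicate: does the planted tract's bp span intersect a
    detected cTOH region, and does the 95% Wald CI of the best-overlapping
    region's odds ratio cover the implied odds ratio?
    """
    tract = RECOVERY_TRACT
    target_or = implied_odds_ratio(tract.p_case, tract.p_control)
    seeds = _child_seeds(seed, n_replicates)
    n_recovered = 0
    n_covered = 0
    n_with_fit = 0
    or_estimates: list[float] = []
    for rep_seed in seeds:
        cfg = SimConfig(planted_tracts=(tract,), seed=rep_seed)
        cohort, regions, results = run_case_control_replicate(cfg)
        lo_bp, hi_bp = cohort.tract_bp_span(tract)
        best = None
        best_overlap = 0
        for region in regions:
            if region.chrom != tract.chrom:
                continue
            ov = min(region.end_bp, hi_bp) - max(region.start_bp, lo_bp)
            if ov > best_overlap:
                best_overlap = ov
                best = region
        if best is None:
            continue
        n_recovered += 1
        row = results[results["region_id"] == best.region_id].iloc[0]
        if row["converged"] and np.isfinite(row["ci_low"]):
            n_with_fit += 1
            or_estimates.append(float(row["odds_ratio"]))
            if row["ci_low"] <= target_or <= row["ci_high"]:
                n_covered += 1
    return {
        "n_replicates": n_replicates,
        "implied_or": target_or,
        "recovery_rate": n_recovered / n_replicates,
        "ci_coverage_rate": n_covered / n_with_fit if n_with_fit else float("nan"),
        "n_with_fit": n_with_fit,
        "mean_or": float(np.mean(or_estimates)) if or_estimates else float("nan"),
    }


def null_calibration_study(n_runs: int = 100, seed: int = 0) -> dict:
    """Calibration of per-region Wald p-values with no true association.

    Eight tracts are planted at equal case/control carrier frequency and the
    phenotype labels are additionally permuted, so every region is null.
    Reports the fraction of runs whose p-values pass a KS uniformity test at
    the 0.01 level, and the overall fraction of regions reaching q < 0.05.
    """
    seeds = _child_seeds(seed, 2 * n_runs)
    n_ks_pass = 0
    n_runs_with_regions = 0
    n_tests = 0
    n_q_positive = 0
    all_p: list[float] = []
    for i in range(n_runs):
        cfg = SimConfig(planted_tracts=NULL_TRACTS, seed=seeds[2 * i])
        _cohort, _regions, results = run_case_control_replicate(
            cfg, permute_phenotype=True, permute_seed=seeds[2 * i + 1]
        )
        p = results.loc[results["converged"], "p_value"].dropna().to_numpy()
        q = results.loc[results["converged"], "fdr_q"].dropna().to_numpy()
        if len(p) < 3:
            continue
        n_runs_with_regions += 1
        all_p.extend(p.tolist())
        if kstest(p, "uniform").pvalue > 0.01:
            n_ks_pass += 1
        n_tests += len(q)
        n_q_positive += int((q < 0.05).sum())
    return {
        "n_runs": n_runs_with_regions,
        "ks_pass_rate": n_ks_pass / n_runs_with_regions
        if n_runs_with_regions
        else float("nan"),
        "q_positive_rate": n_q_positive / n_tests if n_tests else float("nan"),
        "n_tests": n_tests,
        "pooled_p_mean": float(np.mean(all_p)) if all_p else float("nan"),
    }


# ---------------------------------------------------------------------------
# oracle-agreement and correctness studies (shared by tests and the
# acceptance script)
# ---------------------------------------------------------------------------


def oracle_agreement_study(
    seed: int = 0,
    n_rows: int = 1000,
    row_len: int = 500,
    n_intervals: int = 2000,
    n_indels: int = 800,
) -> dict:
    """Exact-agreement rates of the optimized callers against naive oracles.

    TOH caller vs the every-window oracle on random genotype rows; cTOH
    builder vs a direct maximal-run scan on random coverage tracks; interval
    intersection vs the all-pairs definition; indel clustering vs
    union-find transitive closure.  All rates should be exactly 1.0.
    """
    import pandas as pd

    from .core import HET, HOM_A, HOM_B, MISSING
    from .ctoh import define_ctohs
    from .integration import GenomicInterval, IndelCall, cluster_indels, intersect
    from .toh import TOHParams, call_tohs
    from .validation import (
        all_pairs_intersect,
        brute_force_coverage_runs,
        brute_force_toh_windows,
        union_find_clusters,
    )

    rng = np.random.default_rng(seed)

    # --- TOH caller -------------------------------------------------------
    markers = pd.DataFrame(
        {
            "chrom": ["chr1"] * row_len,
            "snp_id": [f"s{i}" for i in range(row_len)],
            "bp": np.arange(1, row_len + 1) * 10,
        }
    )
    params = TOHParams(min_snps=25, max_het=1, max_missing=2)
    n_match = 0
    for _ in range(n_rows):
        row = rng.choice(
            [HOM_A, HOM_B, HET, MISSING], size=row_len, p=[0.44, 0.44, 0.06, 0.06]
        ).astype(np.int8)
        got = [(c.start, c.end) for c in call_tohs(row, markers, params)]
        want = sorted(
            brute_force_toh_windows(
                row == HET, row == MISSING, params.max_het, params.max_missing,
                params.min_snps,
            )
        )
        n_match += got == want
    toh_rate = n_match / n_rows

    # --- cTOH builder -----------------------------------------------------
    m = 2000
    map2 = pd.DataFrame(
        {
            "chrom": ["chr1"] * (m // 2) + ["chr2"] * (m // 2),
            "snp_id": [f"t{i}" for i in range(m)],
            "bp": np.r_[np.arange(1, m // 2 + 1), np.arange(1, m // 2 + 1)] * 7,
        }
    )
    chrom_arr = map2["chrom"].to_numpy()
    n_match = 0
    n_tracks = 50
    for _ in range(n_tracks):
        cov = rng.integers(0, 16, size=m)
        got = [(r.start, r.end) for r in define_ctohs(cov, map2, 10, 20)]
        want = brute_force_coverage_runs(cov, chrom_arr, 10, 20)
        n_match += got == want
    ctoh_rate = n_match / n_tracks

    # --- interval intersection ---------------------------------------------
    def random_intervals(k, tag):
        out = []
        for i in range(k):
            chrom = f"chr{int(rng.integers(1, 4))}"
            start = int(rng.integers(0, 100_000))
            length = int(rng.integers(1, 3_000))
            out.append(GenomicInterval(chrom, start, start + length, tag, f"{tag}{i}"))
        return out

    q = random_intervals(n_intervals // 2, "q")
    s = random_intervals(n_intervals // 2, "s")
    got_pairs = {(a.label, b.label) for a, b in intersect(q, s)}
    want_pairs = {(a.label, b.label) for a, b in all_pairs_intersect(q, s)}
    intersect_ok = float(got_pairs == want_pairs)

    # --- indel clustering ---------------------------------------------------
    samples = [f"ex{i}" for i in range(1, 6)]
    calls = [
        IndelCall(
            samples[int(rng.integers(5))],
            f"chr{int(rng.integers(1, 3))}",
            int(rng.integers(0, 150_000)),
            int(rng.integers(1, 192)),
            "deletion" if rng.random() < 0.5 else "insertion",
        )
        for _ in range(n_indels)
    ]
    key = lambda c: (c.sample, c.chrom, c.start, c.length, c.kind)
    got_groups = {
        frozenset(key(m_) for m_ in cl.members)
        for cl in cluster_indels(calls, merge_window=10)
    }
    want_groups = {
        frozenset(key(calls[i]) for i in grp)
        for grp in union_find_clusters(calls, merge_window=10)
    }
    cluster_ok = float(got_groups == want_groups)

    return {
        "toh_agreement": toh_rate,
        "ctoh_agreement": ctoh_rate,
        "intersect_agreement": intersect_ok,
        "cluster_agreement": cluster_ok,
        "n_rows": n_rows,
    }


def statistical_correctness_study(max_total: int = 200, seed: int = 0) -> dict:
    """Maximum deviations of the statistical primitives from closed forms.

    The exact HWE test is compared with the direct-enumeration oracle over
    every admissible (minor-allele count, het count) configuration up to
    ``max_total`` individuals (the homA/homB-swapped half is covered by the
    test's symmetry property); the logistic fit with the closed-form 2x2 log
    odds ratio and Woolf SE; BH q-values with the explicit step-up formula;
    and the Wald p at |z| = 1.959964 with 0.05.
    """
    from .association import bh_fdr, fit_logistic, wald_test
    from .qc import hwe_exact_test
    from .validation import (
        hwe_enumeration_pvalue,
        normal_tail_quadrature,
        stepup_bh,
        woolf_2x2,
    )

    rng = np.random.default_rng(seed)

    hwe_err = 0.0
    n_hwe = 0
    for n in range(1, max_total + 1):
        for na in range(0, n + 1):
            for b in range(na % 2, na + 1, 2):
                hom_minor = (na - b) // 2
                hom_major = n - b - hom_minor
                p1 = hwe_exact_test(hom_minor, b, hom_major)
                p2 = hwe_enumeration_pvalue(hom_minor, b, hom_major)
                err = abs(p1 - p2)
                if err > hwe_err:
                    hwe_err = err
                n_hwe += 1

    beta_err = se_err = 0.0
    cells = [5, 12, 30, 70, 90, 150]
    for a in cells:
        for b in cells:
            for c in cells:
                for d in cells:
                    y = np.r_[np.ones(a + b), np.zeros(c + d)]
                    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
                    fit = fit_logistic(y, np.column_stack([np.ones_like(y), x]))
                    eb, es = woolf_2x2(a, b, c, d)
                    beta_err = max(beta_err, abs(fit.beta[1] - eb))
                    se_err = max(se_err, abs(fit.se[1] - es))

    bh_err = 0.0
    for _ in range(200):
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 50)))
        bh_err = max(bh_err, float(np.max(np.abs(bh_fdr(p) - stepup_bh(p)))))

    wald_err = abs(wald_test(1.959964, 1.0) - 0.05)
    quad_err = 0.0
    for _ in range(50):
        z = float(rng.uniform(-4, 4))
        quad_err = max(
            quad_err, abs(wald_test(z if z else 0.1, 1.0) - normal_tail_quadrature(z if z else 0.1))
        )

    return {
        "hwe_max_abs_error": hwe_err,
        "n_hwe_configs": n_hwe,
        "logistic_max_beta_error": beta_err,
        "logistic_max_se_error": se_err,
        "bh_max_abs_error": bh_err,
        "wald_error_at_z196": wald_err,
        "wald_max_quadrature_error": quad_err,
    }


def integration_truth_study(seed: int = 0) -> dict:
    """Shortlist recovery on a synthetic exome set with planted truth and
    decoys: the shortlist must equal the recorded truth exactly, and every
    decoy gene (too few samples / no repeat / outside regions) must be
    absent."""
    from .integration import (
        GenomicInterval,
        cluster_indels,
        recurrent_indels,
        shortlist_genes,
    )
    from .synthetic import ExomeConfig, simulate_exome_features

    regions = [
        GenomicInterval("chr1", 1_000_000, 1_800_000, "ctoh", "ctoh_0001"),
        GenomicInterval("chr2", 4_000_000, 4_700_000, "ctoh", "ctoh_0002"),
        GenomicInterval("chr3", 2_500_000, 3_200_000, "ctoh", "ctoh_0003"),
    ]
    cfg = ExomeConfig(seed=seed)
    exome = simulate_exome_features(cfg, regions)
    clusters = cluster_indels(exome.indels, merge_window=10)
    retained = recurrent_indels(clusters, exome.repeats, min_samples=cfg.min_samples)
    shortlist = shortlist_genes(exome.genes, regions, retained, exome.repeats)
    got = sorted(e.gene.symbol for e in shortlist)
    decoys_present = [g for g in got if "DECOY" in g]
    return {
        "shortlist": got,
        "truth": exome.truth_shortlist,
        "exact_match": float(got == exome.truth_shortlist),
        "decoys_excluded": float(not decoys_present),
    }


def determinism_study(seed: int = 0, workdir: str | None = None) -> dict:
    """Run the full pipeline twice with one seed and byte-compare every
    tabular output (the run log carries timestamps and is exempt)."""
    import filecmp
    import os
    import tempfile

    from .pipeline import default_config, run_all

    base = workdir or tempfile.mkdtemp(prefix="tohscan_det_")
    d1 = os.path.join(base, "run_a")
    d2 = os.path.join(base, "run_b")
    run_all(default_config(seed), d1)
    run_all(default_config(seed), d2)
    files = sorted(f for f in os.listdir(d1) if f != "runlog.txt")
    identical = all(
        filecmp.cmp(os.path.join(d1, f), os.path.join(d2, f), shallow=False)
        for f in files
    )
    return {"identical": float(identical), "n_files": len(files)}
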