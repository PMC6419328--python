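"""TOH calling: forced examples, maximality oracle, invariances."""

import numpy as np
import pandas as pd
import pytest

from tohscan.core import HET, HOM_A, HOM_B, MISSING, DataError
from tohscan.toh import TOHParams, call_tohs, toh_length_summary
from tohscan.validation import brute_force_toh_windows

from conftest import make_markers


def row_of(spec: str) -> np.ndarray:
    """'A'/'B' hom, 'h' het, '.' missing."""
    table = {"A": HOM_A, "B": HOM_B, "h": HET, ".": MISSING}
    return np.array([table[c] for c in spec], dtype=np.int8)


def spans(calls):
    return [(c.start, c.end) for c in calls]


def test_all_het_row_has_no_tracts():
    row = np.full(250, HET, dtype=np.int8)
    assert call_tohs(row, make_markers(250), TOHParams(min_snps=10)) == []


def test_single_forced_run():
    row = np.r_[
        np.full(20, HET), np.full(150, HOM_A), np.full(20, HET)
    ].astype(np.int8)
    calls = call_tohs(row, make_markers(190), TOHParams(min_snps=100, max_het=0))
    assert len(calls) == 1
    (c,) = calls
    assert (c.start, c.end, c.n_snps, c.n_hom) == (20, 169, 150, 150)
    assert (c.start_bp, c.end_bp) == (210, 1700)


def test_tracts_never_start_or_end_on_interruptions():
    row = row_of("hAAAA.AAAAh..AAAAAAAh")
    calls = call_tohs(row, make_markers(len(row)), TOHParams(min_snps=4, max_missing=2))
    for c in calls:
        assert row[c.start] in (HOM_A, HOM_B)
        assert row[c.end] in (HOM_A, HOM_B)


def test_matches_every_window_oracle(rng):
    markers = make_markers(150)
    for _ in range(400):
        probs = rng.dirichlet([5, 5, 1.2, 0.8])
        row = rng.choice([HOM_A, HOM_B, HET, MISSING], size=150, p=probs).astype(np.int8)
        params = TOHParams(
            min_snps=int(rng.integers(1, 25)),
            max_het=int(rng.integers(0, 3)),
            max_missing=int(rng.integers(0, 4)),
        )
        got = spans(call_tohs(row, markers, params))
        want = sorted(
            brute_force_toh_windows(
                row == HET, row == MISSING, params.max_het, params.max_missing,
                params.min_snps,
            )
        )
        assert got == want


def test_min_snps_monotonicity(rng):
    markers = make_markers(200)
    for _ in range(50):
        row = rng.choice(
            [HOM_A, HOM_B, HET, MISSING], size=200, p=[0.45, 0.45, 0.05, 0.05]
        ).astype(np.int8)
        loose = spans(call_tohs(row, markers, TOHParams(min_snps=10, max_missing=2)))
        strict = spans(call_tohs(row, markers, TOHParams(min_snps=30, max_missing=2)))
        assert len(strict) <= len(loose)
        for s in strict:
            assert any(l[0] <= s[0] and s[1] <= l[1] for l in loose)


def test_allele_relabel_invariance(rng):
    markers = make_markers(200)
    for _ in range(30):
        row = rng.choice(
            [HOM_A, HOM_B, HET, MISSING], size=200, p=[0.45, 0.45, 0.06, 0.04]
        ).astype(np.int8)
        swapped = row.copy()
        swapped[row == HOM_A] = HOM_B
        swapped[row == HOM_B] = HOM_A
        params = TOHParams(min_snps=15, max_missing=2)
        assert spans(call_tohs(row, markers, params)) == spans(
            call_tohs(swapped, markers, params)
        )


def test_no_tract_contains_another_and_zero_allowance_disjoint(rng):
    markers = make_markers(300)
    for _ in range(40):
        row = rng.choice(
            [HOM_A, HOM_B, HET, MISSING], size=300, p=[0.46, 0.46, 0.04, 0.04]
        ).astype(np.int8)
        got = spans(call_tohs(row, markers, TOHParams(min_snps=10, max_missing=3)))
        for i, a in enumerate(got):
            for b in got[i + 1 :]:
                assert not (a[0] <= b[0] and b[1] <= a[1])
                assert not (b[0] <= a[0] and a[1] <= b[1])
        strict = spans(
            call_tohs(row, markers, TOHParams(min_snps=10, max_het=0, max_missing=0))
        )
        for a, b in zip(strict, strict[1:]):
            assert a[1] < b[0]


def test_tracts_do_not_cross_chromosomes():
    markers = pd.concat(
        [make_markers(100, "chr1"), make_markers(100, "chr2")], ignore_index=True
    )
    row = np.full(200, HOM_A, dtype=np.int8)
    calls = call_tohs(row, markers, TOHParams(min_snps=50))
    assert spans(calls) == [(0, 99), (100, 199)]
    assert [c.chrom for c in calls] == ["chr1", "chr2"]


def test_unsorted_map_rejected():
    markers = make_markers(50)
    markers.loc[10, "bp"] = 5  # break monotonicity
    with pytest.raises(DataError):
        call_tohs(np.full(50, HOM_A, dtype=np.int8), markers, TOHParams(min_snps=5))


def test_length_summary(rng):
    empty = toh_length_summary([])
    assert empty.loc["snp_length", "count"] == 0
    markers = make_markers(400)
    row = np.r_[np.full(120, HOM_A), np.full(280, HET)].astype(np.int8)
    (single,) = call_tohs(row, markers, TOHParams(min_snps=100))
    summary = toh_length_summary([single])
    for stat in ("min", "max", "mean", "median"):
        assert summary.loc["snp_length", stat] == 120
    # many calls vs direct descriptive statistics
    calls = []
    for _ in range(50):
        r = rng.choice([HOM_A, HET], size=400, p=[0.9, 0.1]).astype(np.int8)
        calls.extend(call_tohs(r, markers, TOHParams(min_snps=20)))
    summary = toh_length_summary(calls)
    lengths = np.array([c.n_snps for c in calls])
    assert summary.loc["snp_length", "mean"] == pytest.approx(lengths.mean())
    assert summary.loc["snp_length", "sd"] == pytest.approx(lengths.std(ddof=1))
    assert summary.loc["snp_length", "q3"] == pytest.approx(np.percentile(lengths, 75))
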