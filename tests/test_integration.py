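"""Interval intersection, indel clustering, recurrence and gene shortlist."""

import numpy as np
import pytest

from tohscan.core import DataError
from tohscan.integration import (
    GeneModel,
    GenomicInterval,
    IndelCall,
    cluster_indels,
    intersect,
    ir_summary,
    recurrent_indels,
    shortlist_genes,
)
from tohscan.validation import all_pairs_intersect, union_find_clusters


def iv(chrom, start, end, cls="x", label=""):
    return GenomicInterval(chrom, start, end, cls, label)


# ---------------------------------------------------------------------------
# intersect
# ---------------------------------------------------------------------------


def test_intersect_examples():
    assert intersect([iv("chr1", 0, 10)], [iv("chr1", 20, 30)]) == []
    assert intersect([iv("chr1", 0, 10)], [iv("chr2", 0, 10)]) == []
    same = iv("chr1", 5, 9, label="z")
    assert intersect([same], [same]) == [(same, same)]
    # touching half-open intervals do not overlap
    assert intersect([iv("chr1", 0, 5)], [iv("chr1", 5, 9)]) == []


def test_intersect_matches_all_pairs_and_is_symmetric(rng):
    def rand(k, tag):
        out = []
        for i in range(k):
            start = int(rng.integers(0, 5000))
            out.append(
                iv(f"chr{int(rng.integers(1, 4))}", start,
                   start + int(rng.integers(1, 300)), tag, f"{tag}{i}")
            )
        return out

    a, b = rand(400, "a"), rand(400, "b")
    got = {(q.label, s.label) for q, s in intersect(a, b)}
    want = {(q.label, s.label) for q, s in all_pairs_intersect(a, b)}
    assert got == want
    flipped = {(s.label, q.label) for q, s in intersect(b, a)}
    assert flipped == got


def test_intersect_output_order_deterministic(rng):
    a = [iv("chr1", i * 5, i * 5 + 20, "a", f"a{i}") for i in range(30)]
    b = [iv("chr1", i * 7, i * 7 + 15, "b", f"b{i}") for i in range(30)]
    expected = intersect(a, b)
    for _ in range(5):
        sa = list(a)
        sb = list(b)
        rng.shuffle(sa)
        rng.shuffle(sb)
        assert intersect(sa, sb) == expected


def test_malformed_interval_rejected():
    with pytest.raises(DataError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(DataError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(DataError):
        GenomicInterval("", 0, 5)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def indel(sample, start, length=5, chrom="chr1"):
    return IndelCall(sample, chrom, start, length, "deletion")


def test_cluster_singleton_and_colocated():
    (single,) = cluster_indels([indel("s1", 100)])
    assert single.n_samples == 1
    calls = [indel(f"s{i}", 500) for i in range(1, 4)]
    (cl,) = cluster_indels(calls)
    assert cl.n_samples == 3
    assert cl.samples == ("s1", "s2", "s3")


def test_cluster_matches_union_find(rng):
    calls = [
        indel(
            f"s{int(rng.integers(1, 6))}",
            int(rng.integers(0, 3000)),
            int(rng.integers(1, 40)),
            f"chr{int(rng.integers(1, 3))}",
        )
        for _ in range(400)
    ]
    key = lambda c: (c.sample, c.chrom, c.start, c.length)
    for w in (0, 5, 25):
        got = {frozenset(key(m) for m in cl.members) for cl in cluster_indels(calls, w)}
        want = {
            frozenset(key(calls[i]) for i in grp)
            for grp in union_find_clusters(calls, w)
        }
        assert got == want


def test_zero_window_groups_exactly_overlapping():
    a, b, c = indel("s1", 0, 5), indel("s2", 4, 5), indel("s3", 9, 5)
    clusters = cluster_indels([a, b, c], merge_window=0)
    groups = sorted(tuple(m.sample for m in cl.members) for cl in clusters)
    assert groups == [("s1", "s2"), ("s3",)]  # [0,5) and [4,9) overlap; [9,14) touches only


def test_raising_window_never_splits_clusters(rng):
    calls = [indel(f"s{i % 4}", int(rng.integers(0, 800)), 3) for i in range(120)]
    key = lambda c: (c.sample, c.start)
    small = [
        frozenset(key(m) for m in cl.members) for cl in cluster_indels(calls, 2)
    ]
    big = [frozenset(key(m) for m in cl.members) for cl in cluster_indels(calls, 30)]
    for grp in small:
        assert any(grp <= g for g in big)
    with pytest.raises(DataError):
        cluster_indels(calls, merge_window=-1)


# ---------------------------------------------------------------------------
# recurrence filter and shortlist
# ---------------------------------------------------------------------------


def test_recurrence_requires_both_conjuncts():
    repeats = [iv("chr1", 90, 600, "inverted", "rep1")]
    in_repeat_2 = cluster_indels([indel("s1", 100), indel("s2", 100)])
    in_repeat_3 = cluster_indels([indel(f"s{i}", 100) for i in range(3)])
    no_repeat_3 = cluster_indels([indel(f"s{i}", 5000) for i in range(3)])
    assert recurrent_indels(in_repeat_2, repeats, 3) == []
    assert recurrent_indels(no_repeat_3, repeats, 3) == []
    assert len(recurrent_indels(in_repeat_3, repeats, 3)) == 1


def test_shortlist_requires_region_overlap_and_is_order_invariant(rng):
    regions = [iv("chr1", 0, 10_000, "ctoh", "ctoh_1")]
    genes = [
        GeneModel("INSIDE", "chr1", 1000, 3000),
        GeneModel("OUTSIDE", "chr1", 50_000, 60_000),
    ]
    repeats = [
        iv("chr1", 1900, 2600, "inverted", "rep_in"),
        iv("chr1", 54_000, 55_000, "simple", "rep_out"),
    ]
    calls = [indel(f"s{i}", 2000) for i in range(3)] + [
        indel(f"s{i}", 54_500) for i in range(3)
    ]
    clusters = recurrent_indels(cluster_indels(calls), repeats, 3)
    entries = shortlist_genes(genes, regions, clusters, repeats)
    assert [e.gene.symbol for e in entries] == ["INSIDE"]
    assert entries[0].samples == ("s0", "s1", "s2")
    assert entries[0].region_id == "ctoh_1"
    # input record order must not matter
    for _ in range(3):
        g2, r2, c2 = list(genes), list(repeats), list(clusters)
        rng.shuffle(g2)
        rng.shuffle(r2)
        rng.shuffle(c2)
        assert shortlist_genes(g2, regions, c2, r2) == entries


def test_ir_summary_counts_and_oracle():
    ctohs = [iv("chr1", 0, 10_000, "ctoh", "r1"), iv("chr2", 0, 10_000, "ctoh", "r2")]
    genes = [GeneModel("G1", "chr1", 400, 900), GeneModel("G2", "chr1", 5000, 6000)]
    repeats = [
        iv("chr1", 100, 600, "inverted", "a"),     # in region, hits G1
        iv("chr1", 7000, 7500, "inverted", "b"),   # in region, hits nothing
        iv("chr1", 20_000, 21_000, "inverted", "c"),  # outside regions
        iv("chr1", 200, 800, "simple", "d"),       # wrong class
    ]
    df = ir_summary(repeats, ctohs, genes)
    assert list(df["chrom"]) == ["chr1"]  # chr2 has no qualifying repeat
    row = df.iloc[0]
    assert row["n_irs"] == 2
    assert row["min_bp"] == 500 and row["max_bp"] == 500
    assert row["mean_bp"] == 500.0
    assert row["n_genes_with_irs"] == 1

    single = ir_summary([iv("chr3", 0, 500, "inverted")], [iv("chr3", 0, 1000, "ctoh")], [])
    assert single.iloc[0]["min_bp"] == single.iloc[0]["max_bp"] == 500


def test_ir_summary_random_vs_direct_count(rng):
    ctohs = [iv("chr1", 2000, 9000, "ctoh", "r")]
    genes = [GeneModel(f"G{i}", "chr1", i * 700, i * 700 + 400) for i in range(12)]
    repeats = [
        iv("chr1", int(s), int(s) + int(l), "inverted", f"rep{i}")
        for i, (s, l) in enumerate(
            zip(rng.integers(0, 12_000, 60), rng.integers(39, 400, 60))
        )
    ]
    df = ir_summary(repeats, ctohs, genes)
    inside = [r for r in repeats if r.start < 9000 and 2000 < r.end]
    assert df.iloc[0]["n_irs"] == len(inside)
    hit = {
        g.symbol
        for g in genes
        for r in inside
        if r.start < g.end and g.start < r.end
    }
    assert df.iloc[0]["n_genes_with_irs"] == len(hit)
    assert df.iloc[0]["mean_bp"] == pytest.approx(
        np.mean([r.length for r in inside])
    )
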