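"""Integration of repeat elements, recurrent indels and genes with cTOH regions.

The final stage of the pipeline: given the significantly associated common-TOH
regions, per-sample exome indel calls and repeat-element annotations (inverted
and simple repeats, consumed as intervals), shortlist the genes that

1. lie inside a significant cTOH region,
2. harbour an indel cluster recurring in at least ``min_samples`` distinct
   exome samples, and
3. whose supporting indel cluster overlaps an inverted or simple repeat.

All coordinates are 0-based half-open.  Strand is ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DataError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span ``[start, end)`` with a class tag and payload label."""

    chrom: str
    start: int
    end: int
    cls: str = "region"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("interval with empty chromosome label")
        if self.start < 0 or self.end <= self.start:
            raise DataError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class IndelCall:
    """One insertion/deletion call in one exome sample.

    The affected span is taken as ``[start, start + length)`` for both
    insertions and deletions; only span and length enter the analysis.
    """

    sample: str
    chrom: str
    start: int
    length: int
    kind: str = "deletion"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise DataError("indel length must be >= 1")
        if self.kind not in ("insertion", "deletion"):
            raise DataError(f"unknown indel type {self.kind!r}")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.start + self.length, "indel", self.sample
        )


@dataclass(frozen=True, order=True)
class GeneModel:
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"gene {self.symbol} has end <= start")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, "gene", self.symbol)


@dataclass(frozen=True)
class IndelCluster:
    """A single-linkage group of indel calls on one chromosome."""

    chrom: str
    start: int
    end: int
    members: tuple[IndelCall, ...]

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(sorted({m.sample for m in self.members}))

    @property
    def n_samples(self) -> int:
        return len({m.sample for m in self.members})

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, "indel_cluster")


@dataclass(frozen=True)
class ShortlistEntry:
    gene: GeneModel
    samples: tuple[str, ...]
    clusters: tuple[IndelCluster, ...]
    repeats: tuple[GenomicInterval, ...]
    region_id: str


# ---------------------------------------------------------------------------
# interval intersection (sort-and-sweep)
# ---------------------------------------------------------------------------

def intersect(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All overlapping (query, subject) pairs via a sort-and-sweep.

    Two half-open intervals overlap when ``q.start < s.end and
    s.start < q.end`` on the same chromosome.  The returned list is sorted by
    (chromosome, query start/end/label, subject start/end/label) so the output
    order is deterministic regardless of input order.
    """
    events: list[tuple[str, int, int, int, int]] = []
    # event: (chrom, pos, kind, side, idx); closes (kind 0) processed before
    # opens (kind 1) at the same position so touching intervals do not pair.
    for side, ivs in ((0, query), (1, subject)):
        for i, iv in enumerate(ivs):
            if not isinstance(iv, GenomicInterval):
                raise DataError("intersect expects GenomicInterval inputs")
            events.append((iv.chrom, iv.start, 1, side, i))
            events.append((iv.chrom, iv.end, 0, side, i))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    active: tuple[dict[int, GenomicInterval], dict[int, GenomicInterval]] = ({}, {})
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    current_chrom: str | None = None
    for chrom, _pos, kind, side, idx in events:
        if chrom != current_chrom:
            active[0].clear()
            active[1].clear()
            current_chrom = chrom
        iv = (query if side == 0 else subject)[idx]
        if kind == 0:
            active[side].pop(idx, None)
        else:
            other = active[1 - side]
            if side == 0:
                pairs.extend((iv, s) for s in other.values())
            else:
                pairs.extend((q, iv) for q in other.values())
            active[side][idx] = iv
    pairs.sort(
        key=lambda p: (
            p[0].chrom,
            p[0].start,
            p[0].end,
            p[0].label,
            p[1].start,
            p[1].end,
            p[1].label,
        )
    )
    return pairs


# ---------------------------------------------------------------------------
# indel clustering and recurrence
# ---------------------------------------------------------------------------

def cluster_indels(
    indels: Iterable[IndelCall], merge_window: int = 10
) -> list[IndelCluster]:
    """Single-linkage clustering of indel spans across samples.

    Two calls on the same chromosome are linked when their spans, each widened
    by ``merge_window`` bp, strictly overlap — i.e. the gap between them is
    smaller than ``merge_window``.  With ``merge_window=0`` exactly the calls
    with overlapping spans are grouped.  Clusters are returned sorted by
    (chromosome, start, end).
    """
    if merge_window < 0:
        raise DataError("merge_window must be non-negative")
    by_chrom: dict[str, list[IndelCall]] = {}
    for call in indels:
        by_chrom.setdefault(call.chrom, []).append(call)
    clusters: list[IndelCluster] = []
    for chrom in sorted(by_chrom):
        calls = sorted(by_chrom[chrom], key=lambda c: (c.start, c.length, c.sample))
        group: list[IndelCall] = []
        group_end = None
        for call in calls:
            if group and call.start < group_end + merge_window:
                group.append(call)
                group_end = max(group_end, call.start + call.length)
            else:
                if group:
                    clusters.append(
                        IndelCluster(chrom, group[0].start, group_end, tuple(group))
                    )
                group = [call]
                group_end = call.start + call.length
        if group:
            clusters.append(IndelCluster(chrom, group[0].start, group_end, tuple(group)))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.end))
    return clusters


def recurrent_indels(
    clusters: Sequence[IndelCluster],
    repeats: Sequence[GenomicInterval],
    min_samples: int = 3,
) -> list[IndelCluster]:
    """Clusters recurring in >= ``min_samples`` distinct samples that overlap
    at least one (inverted or simple) repeat interval."""
    spans = [c.interval() for c in clusters]
    overlapping = {id(q) for q, _s in intersect(spans, list(repeats))}
    kept = [
        c
        for c, span in zip(clusters, spans)
        if c.n_samples >= min_samples and id(span) in overlapping
    ]
    return kept


# ---------------------------------------------------------------------------
# gene shortlist and repeat summaries
# ---------------------------------------------------------------------------

def shortlist_genes(
    genes: Sequence[GeneModel],
    significant_ctohs: Sequence[GenomicInterval],
    clusters: Sequence[IndelCluster],
    repeats: Sequence[GenomicInterval],
) -> list[ShortlistEntry]:
    """Genes inside a significant cTOH that carry a retained indel cluster.

    ``clusters`` should already have passed :func:`recurrent_indels`.  Each
    entry records the supporting samples, clusters, overlapping repeats and
    the host region.  Output is sorted by (chromosome, gene start, symbol) and
    is invariant to input record order.
    """
    gene_ivs = [g.interval() for g in genes]
    in_region: dict[int, str] = {}
    for q, s in intersect(gene_ivs, list(significant_ctohs)):
        in_region.setdefault(id(q), s.label)
    cluster_ivs = [c.interval() for c in clusters]
    by_iv_id = {id(iv): c for iv, c in zip(cluster_ivs, clusters)}
    gene_clusters: dict[int, list[IndelCluster]] = {}
    for q, s in intersect(gene_ivs, cluster_ivs):
        gene_clusters.setdefault(id(q), []).append(by_iv_id[id(s)])
    out: list[ShortlistEntry] = []
    for gene, iv in zip(genes, gene_ivs):
        if id(iv) not in in_region or id(iv) not in gene_clusters:
            continue
        sup = sorted(
            set(gene_clusters[id(iv)]), key=lambda c: (c.chrom, c.start, c.end)
        )
        rep = [
            s
            for _q, s in intersect([c.interval() for c in sup], list(repeats))
        ]
        rep = sorted(set(rep))
        samples = tuple(sorted({s for c in sup for s in c.samples}))
        out.append(
            ShortlistEntry(
                gene=gene,
                samples=samples,
                clusters=tuple(sup),
                repeats=tuple(rep),
                region_id=in_region[id(iv)],
            )
        )
    out.sort(key=lambda e: (e.gene.chrom, e.gene.start, e.gene.symbol))
    return out


def ir_summary(
    repeats: Sequence[GenomicInterval],
    ctohs: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    classes: tuple[str, ...] | None = ("inverted",),
) -> pd.DataFrame:
    """Per-chromosome summary of repeats falling inside cTOH regions.

    Restricts ``repeats`` to those overlapping at least one cTOH interval
    (and, when ``classes`` is given, to those class tags), then reports per
    chromosome: repeat count, min/max/mean length, and the number of genes
    overlapped by at least one such repeat.  Chromosomes without qualifying
    repeats are omitted.
    """
    pool = [r for r in repeats if classes is None or r.cls in classes]
    seen: dict[int, GenomicInterval] = {}
    for q, _s in intersect(pool, list(ctohs)):
        seen.setdefault(id(q), q)
    inside = sorted(seen.values())
    gene_ivs = [g.interval() for g in genes]
    genes_hit: dict[str, set[str]] = {}
    for q, s in intersect(inside, gene_ivs):
        genes_hit.setdefault(q.chrom, set()).add(s.label)
    rows = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in inside:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        lengths = np.array([r.length for r in by_chrom[chrom]])
        rows.append(
            {
                "chrom": chrom,
                "n_irs": len(lengths),
                "min_bp": int(lengths.min()),
                "max_bp": int(lengths.max()),
                "mean_bp": float(lengths.mean()),
                "n_genes_with_irs": len(genes_hit.get(chrom, ())),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "n_irs", "min_bp", "max_bp", "mean_bp", "n_genes_with_irs"],
    )
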