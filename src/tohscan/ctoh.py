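"""Common-TOH (cTOH) regions and per-individual carrier status.

A cTOH region is a maximal run of consecutive markers, within one
chromosome, at which at least ``min_subjects`` individuals simultaneously
carry a TOH, retained only when the run spans at least ``min_snps`` markers
(defaults 10 subjects / 100 SNPs).  An individual *carries* a region when
their own TOH calls cover at least ``min_cover_frac`` of its markers; the
resulting binary matrix is the predictor of the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError
from .integration import GenomicInterval
from .toh import TOHCall


@dataclass(frozen=True)
class CTOHRegion:
    """One shared-homozygosity region at marker resolution."""

    region_id: str
    chrom: str
    start: int  # 0-based inclusive marker index into the full map
    end: int
    start_bp: int
    end_bp: int
    n_snps: int
    max_coverage: int
    min_coverage: int

    @property
    def bp_length(self) -> int:
        return self.end_bp - self.start_bp + 1

    def interval(self) -> GenomicInterval:
        """bp-space half-open interval for annotation overlap."""
        return GenomicInterval(
            self.chrom, self.start_bp - 1, self.end_bp, "ctoh", self.region_id
        )


def toh_coverage(tohs: list[TOHCall], marker_map: pd.DataFrame) -> np.ndarray:
    """Per-marker count of distinct individuals whose TOH covers it.

    Overlapping calls from one individual (possible when the het/missing
    allowances let maximal windows overlap) are unioned before counting.
    """
    m = len(marker_map)
    known = set(map(str, marker_map["chrom"].unique()))
    cov = np.zeros(m + 1, dtype=np.int64)
    by_sample: dict[str, list[TOHCall]] = {}
    for t in tohs:
        if t.chrom not in known:
            raise DataError(f"TOH call on unknown chromosome {t.chrom}")
        if not (0 <= t.start <= t.end < m):
            raise DataError("TOH call indices outside the marker map")
        by_sample.setdefault(t.sample_id, []).append(t)
    for calls in by_sample.values():
        calls.sort(key=lambda t: t.start)
        merged_start, merged_end = None, None
        # merging adjacent spans leaves the per-position increments unchanged
        for t in calls:
            if merged_start is None:
                merged_start, merged_end = t.start, t.end
            elif t.start <= merged_end + 1:
                merged_end = max(merged_end, t.end)
            else:
                cov[merged_start] += 1
                cov[merged_end + 1] -= 1
                merged_start, merged_end = t.start, t.end
        if merged_start is not None:
            cov[merged_start] += 1
            cov[merged_end + 1] -= 1
    return np.cumsum(cov[:-1])


def define_ctohs(
    coverage: np.ndarray,
    marker_map: pd.DataFrame,
    min_subjects: int = 10,
    min_snps: int = 100,
) -> list[CTOHRegion]:
    """Maximal runs of markers with coverage >= ``min_subjects``, kept when
    at least ``min_snps`` long; runs never cross chromosome boundaries."""
    coverage = np.asarray(coverage)
    if coverage.shape != (len(marker_map),):
        raise DataError("coverage length does not match the marker map")
    chroms = marker_map["chrom"].to_numpy()
    bp = marker_map["bp"].to_numpy()
    qualifies = coverage >= min_subjects
    # break runs at chromosome boundaries
    boundary = np.zeros(len(chroms), dtype=bool)
    if len(chroms):
        boundary[0] = True
        boundary[1:] = chroms[1:] != chroms[:-1]
    regions: list[CTOHRegion] = []
    i = 0
    m = len(coverage)
    while i < m:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and qualifies[j + 1] and not boundary[j + 1]:
            j += 1
        if j - i + 1 >= min_snps:
            inside = coverage[i : j + 1]
            regions.append(
                CTOHRegion(
                    region_id=f"ctoh_{len(regions) + 1:04d}",
                    chrom=str(chroms[i]),
                    start=i,
                    end=j,
                    start_bp=int(bp[i]),
                    end_bp=int(bp[j]),
                    n_snps=j - i + 1,
                    max_coverage=int(inside.max()),
                    min_coverage=int(inside.min()),
                )
            )
        i = j + 1
    return regions


def assign_carriers(
    regions: list[CTOHRegion],
    tohs: list[TOHCall],
    sample_ids: list[str],
    min_cover_frac: float = 0.9,
) -> pd.DataFrame:
    """Binary individuals x regions carrier matrix.

    An individual carries a region when their (unioned) TOH calls cover at
    least ``min_cover_frac`` of the region's markers.  The SNP-count
    threshold is ``ceil(min_cover_frac * n_snps)`` evaluated with a small
    tolerance so that e.g. 90% of 150 markers is exactly 135.
    """
    if not 0.0 < min_cover_frac <= 1.0:
        raise DataError("min_cover_frac must lie in (0, 1]")
    mat = np.zeros((len(sample_ids), len(regions)), dtype=np.int8)
    order = {s: i for i, s in enumerate(sample_ids)}
    by_sample: dict[str, list[TOHCall]] = {}
    for t in tohs:
        if t.sample_id not in order:
            raise DataError(f"TOH call for unknown sample {t.sample_id}")
        by_sample.setdefault(t.sample_id, []).append(t)
    for r_idx, region in enumerate(regions):
        required = int(np.ceil(min_cover_frac * region.n_snps - 1e-9))
        for sample, calls in by_sample.items():
            covered = _union_overlap(calls, region.start, region.end)
            if covered >= required:
                mat[order[sample], r_idx] = 1
    return pd.DataFrame(
        mat, index=pd.Index(sample_ids, name="sample_id"),
        columns=[r.region_id for r in regions],
    )


def _union_overlap(calls: list[TOHCall], lo: int, hi: int) -> int:
    """Markers in [lo, hi] covered by the union of the calls' index spans."""
    spans = sorted(
        (max(t.start, lo), min(t.end, hi)) for t in calls if t.start <= hi and t.end >= lo
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in spans:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return covered


def regions_table(regions: list[CTOHRegion]) -> pd.DataFrame:
    """Tabular view of regions (region, chrom, span, length bp, No. of SNPs)."""
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start_idx": r.start,
                "end_idx": r.end,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.bp_length,
                "n_snps": r.n_snps,
                "max_coverage": r.max_coverage,
                "min_coverage": r.min_coverage,
            }
            for r in regions
        ],
        columns=[
            "region_id",
            "chrom",
            "start_idx",
            "end_idx",
            "start_bp",
            "end_bp",
            "length_bp",
            "n_snps",
            "max_coverage",
            "min_coverage",
        ],
    )
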