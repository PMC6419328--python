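"""Per-individual tract-of-homozygosity (TOH) calling.

A TOH is a maximal window of consecutive markers on one chromosome that
contains at least ``min_snps`` homozygous calls, at most ``max_het``
heterozygous calls and at most ``max_missing`` missing calls, and that starts
and ends on a homozygous call.  "Maximal" means no valid window strictly
contains it; when the het/missing allowances are positive, two maximal
windows may overlap (they bridge different subsets of the allowed
interruptions), so the caller returns every maximal window rather than an
arbitrary disjoint subset.

The scan works over the positions of the interrupting (het/missing) calls
only: a two-pointer pass finds, for each maximal run of interruptions that
fits the allowances, the widest window around it, trims the endpoints to
homozygous calls, and keeps the windows that are not contained in an earlier
one.  This is O(number of interruptions) per chromosome.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, DataError, GenotypeMatrix


@dataclass(frozen=True)
class TOHParams:
    """Calling thresholds: tract scale in SNPs plus interruption allowances.

    Defaults demand 100 homozygous SNPs with no heterozygote and at most two
    missing calls inside (strict homozygosity while tolerating array
    dropout).  ``min_bp`` optionally adds a physical-length floor (off by
    default).
    """

    min_snps: int = 100
    max_het: int = 0
    max_missing: int = 2
    min_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise DataError("min_snps must be >= 1")
        if self.max_het < 0 or self.max_missing < 0 or self.min_bp < 0:
            raise DataError("allowances must be >= 0")


@dataclass(frozen=True)
class TOHCall:
    """One individual's maximal homozygous run.

    ``start``/``end`` are 0-based inclusive indices into the full marker map;
    ``n_snps`` is the window span (``end - start + 1``), of which ``n_hom``
    are homozygous, ``n_het`` heterozygous and ``n_missing`` missing.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_hom: int
    n_het: int
    n_missing: int


def _maximal_windows(
    is_het: np.ndarray,
    is_missing: np.ndarray,
    max_het: int,
    max_missing: int,
    min_hom: int,
) -> list[tuple[int, int]]:
    """All maximal valid windows of one chromosome row as (start, end) pairs."""
    n = is_het.size
    if n == 0:
        return []
    ev_pos = np.flatnonzero(is_het | is_missing)
    ev_is_het = is_het[ev_pos]
    e = ev_pos.size
    pos = ev_pos.tolist()
    het_flags = ev_is_het.tolist()
    # prefix counts of het events for O(1) window queries
    het_cum = [0]
    for flag in het_flags:
        het_cum.append(het_cum[-1] + (1 if flag else 0))

    # one candidate window per possible run of included interruptions
    raw: set[tuple[int, int]] = set()
    l = 0
    for k in range(e + 1):
        if l < k:
            l = k
        # extend the run of included events while both budgets hold
        while l < e:
            hets = het_cum[l + 1] - het_cum[k]
            miss = (l + 1 - k) - hets
            if hets <= max_het and miss <= max_missing:
                l += 1
            else:
                break
        start = pos[k - 1] + 1 if k > 0 else 0
        end = pos[l] - 1 if l < e else n - 1
        # trim endpoints onto homozygous calls past any included events
        j = k
        while j < l and pos[j] == start:
            start += 1
            j += 1
        j = l - 1
        while j >= k and pos[j] == end:
            end -= 1
            j -= 1
        if start <= end:
            raw.add((start, end))

    # keep only windows not strictly contained in another candidate, then
    # apply the homozygous-call floor (a contained window never out-counts
    # its container, so the filter order is immaterial)
    out: list[tuple[int, int]] = []
    best_end = -1
    for start, end in sorted(raw, key=lambda w: (w[0], -w[1])):
        if end > best_end:
            a = bisect.bisect_left(pos, start)
            b = bisect.bisect_right(pos, end)
            n_hom = (end - start + 1) - (b - a)
            if n_hom >= min_hom:
                out.append((start, end))
            best_end = end
    return out


def call_tohs(
    genotype_row: np.ndarray,
    marker_map: pd.DataFrame,
    params: TOHParams | None = None,
    sample_id: str = "",
) -> list[TOHCall]:
    """Call all maximal TOHs in one individual's genotype row.

    ``marker_map`` must have columns chrom/snp_id/bp, grouped by chromosome
    and sorted by bp within each chromosome; tracts never cross chromosome
    boundaries.
    """
    params = params or TOHParams()
    row = np.asarray(genotype_row)
    if row.ndim != 1 or row.size != len(marker_map):
        raise DataError("genotype row length does not match the marker map")
    chroms = marker_map["chrom"].to_numpy()
    bp = marker_map["bp"].to_numpy()
    calls: list[TOHCall] = []
    start = 0
    n = row.size
    seen: set[str] = set()
    while start < n:
        stop = start
        while stop < n and chroms[stop] == chroms[start]:
            stop += 1
        chrom = str(chroms[start])
        if chrom in seen:
            raise DataError(f"markers for chromosome {chrom} are not contiguous")
        seen.add(chrom)
        seg_bp = bp[start:stop]
        if np.any(np.diff(seg_bp) <= 0):
            raise DataError(f"marker map not sorted by bp on {chrom}")
        seg = row[start:stop]
        is_het = seg == HET
        is_missing = seg == MISSING
        # cheap skip: the largest het-free stretch bounds the homozygous count
        if params.max_het == 0:
            het_idx = np.flatnonzero(is_het)
            bounds = np.r_[-1, het_idx, seg.size]
            if (np.diff(bounds) - 1).max() < params.min_snps:
                start = stop
                continue
        for s, t in _maximal_windows(
            is_het, is_missing, params.max_het, params.max_missing, params.min_snps
        ):
            if params.min_bp and seg_bp[t] - seg_bp[s] + 1 < params.min_bp:
                continue
            window = seg[s : t + 1]
            n_het = int((window == HET).sum())
            n_missing = int((window == MISSING).sum())
            calls.append(
                TOHCall(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=start + s,
                    end=start + t,
                    start_bp=int(seg_bp[s]),
                    end_bp=int(seg_bp[t]),
                    n_snps=t - s + 1,
                    n_hom=(t - s + 1) - n_het - n_missing,
                    n_het=n_het,
                    n_missing=n_missing,
                )
            )
        start = stop
    return calls


def call_tohs_matrix(
    genotypes: GenotypeMatrix, params: TOHParams | None = None
) -> list[TOHCall]:
    """Call TOHs for every individual in a genotype matrix."""
    params = params or TOHParams()
    out: list[TOHCall] = []
    ids = genotypes.samples["sample_id"].to_numpy()
    for i in range(genotypes.n_samples):
        out.extend(
            call_tohs(genotypes.calls[i], genotypes.markers, params, sample_id=str(ids[i]))
        )
    return out


def toh_length_summary(
    calls: list[TOHCall], marker_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Descriptive statistics of tract lengths in SNPs and in bp.

    Returns a two-row frame (one per unit) with count, min, max, mean, SD,
    median and quartiles; an empty call list yields count 0 and NA statistics.
    """
    stats = ["count", "min", "max", "mean", "sd", "median", "q1", "q3"]
    if not calls:
        df = pd.DataFrame(np.nan, index=["snp_length", "bp_length"], columns=stats)
        df["count"] = 0
        return df

    def describe(x: np.ndarray) -> list[float]:
        return [
            len(x),
            float(np.min(x)),
            float(np.max(x)),
            float(np.mean(x)),
            float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
            float(np.median(x)),
            float(np.percentile(x, 25)),
            float(np.percentile(x, 75)),
        ]

    snp_len = np.array([c.n_snps for c in calls])
    bp_len = np.array([c.end_bp - c.start_bp + 1 for c in calls])
    return pd.DataFrame(
        [describe(snp_len), describe(bp_len)],
        index=["snp_length", "bp_length"],
        columns=stats,
    )
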