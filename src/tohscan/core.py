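"""Core containers shared across the pipeline.

Genotypes are stored as an ``(n_samples, n_snps)`` ``int8`` matrix using the
codes below.  ``HOM_A``/``HOM_B`` count copies of allele B (0 and 2), so a
column can be read directly as an additive 0/1/2 coding with ``MISSING``
sentinel ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HOM_A: int = 0  # homozygous for allele A (zero copies of B)
HET: int = 1
HOM_B: int = 2  # homozygous for allele B
MISSING: int = -1

VALID_CODES = frozenset({HOM_A, HET, HOM_B, MISSING})

MARKER_COLUMNS = ("chrom", "snp_id", "bp")
SAMPLE_COLUMNS = ("sample_id", "sex", "phenotype")


class TohscanError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(TohscanError):
    """A configuration value is invalid or internally inconsistent."""


class DataError(TohscanError):
    """An input file or matrix violates its contract."""


@dataclass
class GenotypeMatrix:
    """SNP genotype calls for a cohort plus marker map and phenotypes.

    Parameters
    ----------
    calls
        ``(n_samples, n_snps)`` ``int8`` array with entries in
        ``{HOM_A, HET, HOM_B, MISSING}``.
    samples
        One row per individual with columns ``sample_id`` (str, unique),
        ``sex`` (1 = male, 0 = female) and ``phenotype`` (1 = case,
        0 = control).
    markers
        One row per SNP with columns ``chrom`` (str), ``snp_id`` (str,
        unique) and ``bp`` (1-based position).  Markers must be grouped by
        chromosome with strictly increasing ``bp`` within each chromosome.
    """

    calls: np.ndarray
    samples: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise DataError("genotype calls must be a 2-D array")
        n, m = self.calls.shape
        if len(self.samples) != n:
            raise DataError(
                f"sample table has {len(self.samples)} rows for {n} genotype rows"
            )
        if len(self.markers) != m:
            raise DataError(
                f"marker map has {len(self.markers)} rows for {m} genotype columns"
            )
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise DataError(f"sample table lacks column {col!r}")
        for col in MARKER_COLUMNS:
            if col not in self.markers.columns:
                raise DataError(f"marker map lacks column {col!r}")
        if m and not self.markers["snp_id"].is_unique:
            raise DataError("duplicate SNP ids in marker map")
        if n and not self.samples["sample_id"].is_unique:
            raise DataError("duplicate sample ids")
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        chroms = self.markers["chrom"].to_numpy()
        bp = self.markers["bp"].to_numpy()
        seen: set[str] = set()
        prev = None
        for c in chroms:
            if c != prev:
                if c in seen:
                    raise DataError(f"markers for chromosome {c} are not contiguous")
                seen.add(c)
                prev = c
        for sl in self.chromosome_slices().values():
            d = np.diff(bp[sl])
            if len(d) and not (d > 0).all():
                raise DataError("marker bp not strictly increasing within chromosome")

    # -- basic geometry ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def chromosome_slices(self) -> dict[str, slice]:
        """Map chromosome label -> contiguous slice of marker indices."""
        chroms = self.markers["chrom"].to_numpy()
        out: dict[str, slice] = {}
        if len(chroms) == 0:
            return out
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    # -- per-SNP genotype counts ------------------------------------------
    def genotype_counts(self) -> pd.DataFrame:
        """Per-SNP counts of homA/het/homB/missing calls (vectorised)."""
        g = self.calls
        counts = {
            "n_hom_a": (g == HOM_A).sum(axis=0),
            "n_het": (g == HET).sum(axis=0),
            "n_hom_b": (g == HOM_B).sum(axis=0),
            "n_missing": (g == MISSING).sum(axis=0),
        }
        df = pd.DataFrame(counts)
        df.insert(0, "snp_id", self.markers["snp_id"].to_numpy())
        return df

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/SNP index arrays."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(si, mi)].copy(),
            samples=self.samples.iloc[si].reset_index(drop=True),
            markers=self.markers.iloc[mi].reset_index(drop=True),
        )
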