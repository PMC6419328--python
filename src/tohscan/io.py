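"""Readers and writers for the standard text formats the pipeline exchanges.

PLINK text ``.ped``/``.map`` carries genotypes; BED carries repeats, genes
and cTOH spans (0-based half-open, name field = class/symbol); indel calls
travel as TSV (canonical) or as a minimal VCF dialect where only
CHROM/POS/REF/ALT are consumed, the indel length is ``|len(REF) -
len(ALT)|`` and the source sample is carried in the INFO field.  TSV is the
tabular interchange for everything else.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import HET, HOM_A, HOM_B, MISSING, DataError, GenotypeMatrix
from .integration import GeneModel, GenomicInterval, IndelCall

# ---------------------------------------------------------------------------
# PLINK text .ped / .map
# ---------------------------------------------------------------------------


def read_plink(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read PLINK text pedigree + map files.

    Genotype coding per SNP: allele A is the lexicographically smaller of
    the observed allele symbols (a SNP where only one allele is seen maps to
    homA); '0' denotes a missing allele and any half-missing genotype is
    treated as missing.  PED sex 1=male/2=female maps to 1/0; phenotype
    2=case/1=control maps to 1/0.
    """
    markers = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    if not markers["snp_id"].is_unique:
        raise DataError(f"duplicate SNP ids in {map_path}")
    m = len(markers)
    sample_rows = []
    geno_rows: list[np.ndarray] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise DataError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(fields)}"
                )
            _fid, iid, _pat, _mat, sex, pheno = fields[:6]
            sample_rows.append(
                {
                    "sample_id": iid,
                    "sex": 1 if sex == "1" else 0,
                    "phenotype": 1 if pheno == "2" else 0,
                }
            )
            alleles = fields[6:]
            allele_pairs.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)]
            )
    n = len(sample_rows)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        observed = sorted(
            {a for pairs in allele_pairs for a in pairs[j] if a != "0"}
        )
        if len(observed) > 2:
            raise DataError(
                f"SNP {markers['snp_id'][j]} has more than two alleles: {observed}"
            )
        a_allele = observed[0] if observed else None
        for i, pairs in enumerate(allele_pairs):
            x, y = pairs[j]
            if x == "0" or y == "0":
                continue
            n_a = (x == a_allele) + (y == a_allele)
            calls[i, j] = (HOM_A, HET, HOM_B)[2 - n_a]
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "sex", "phenotype"])
    return GenotypeMatrix(
        calls=calls, samples=samples, markers=markers[["chrom", "snp_id", "bp"]]
    )


def write_plink(genotypes: GenotypeMatrix, ped_path: str, map_path: str) -> None:
    """Write PLINK text files using allele symbols 'A'/'B' and '0 0' missing."""
    genotypes.markers.assign(cm=0)[["chrom", "snp_id", "cm", "bp"]].to_csv(
        map_path, sep="\t", header=False, index=False
    )
    code_to_pair = {HOM_A: "A A", HET: "A B", HOM_B: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i in range(genotypes.n_samples):
            s = genotypes.samples.iloc[i]
            lead = [
                "FAM",
                str(s["sample_id"]),
                "0",
                "0",
                "1" if s["sex"] == 1 else "2",
                "2" if s["phenotype"] == 1 else "1",
            ]
            geno = [code_to_pair[int(c)] for c in genotypes.calls[i]]
            fh.write(" ".join(lead + geno) + "\n")


def write_phenotypes(genotypes: GenotypeMatrix, path: str) -> None:
    genotypes.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed(path: str, cls: str | None = None) -> list[GenomicInterval]:
    """Read a 3+ column BED file into 0-based half-open intervals.

    The name column (4th) becomes the payload label; when ``cls`` is None
    the 5th column, if present, is used as the class tag (our BED writer
    stores it there), otherwise the label doubles as the class.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out: list[GenomicInterval] = []
    for row in df.itertuples(index=False):
        vals = list(row)
        if len(vals) < 3:
            raise DataError(f"{path}: BED needs at least 3 columns")
        chrom, start, end = vals[0], int(vals[1]), int(vals[2])
        if start < 0 or end <= start:
            raise DataError(f"{path}: malformed interval {chrom}:{start}-{end}")
        label = vals[3] if len(vals) > 3 and pd.notna(vals[3]) else ""
        tag = cls
        if tag is None:
            if len(vals) > 4 and pd.notna(vals[4]):
                tag = vals[4]
            else:
                tag = label or "region"
        out.append(GenomicInterval(chrom, start, end, tag, label))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str) -> None:
    """Write intervals as 5-column BED (chrom, start, end, name, class)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{iv.cls}\n")


def read_genes_bed(path: str) -> list[GeneModel]:
    return [
        GeneModel(iv.label or f"gene_{i}", iv.chrom, iv.start, iv.end)
        for i, iv in enumerate(read_bed(path, cls="gene"))
    ]


def write_genes_bed(genes: Sequence[GeneModel], path: str) -> None:
    write_bed([g.interval() for g in genes], path)


# ---------------------------------------------------------------------------
# indel calls: TSV (canonical) and minimal VCF
# ---------------------------------------------------------------------------

INDEL_COLUMNS = ["sample", "chrom", "start0", "length", "type"]


def read_indels_tsv(path: str) -> list[IndelCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(INDEL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return [
        IndelCall(r.sample, r.chrom, int(r.start0), int(r.length), r.type)
        for r in df.itertuples(index=False)
    ]


def write_indels_tsv(indels: Iterable[IndelCall], path: str) -> None:
    pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "start0": c.start,
                "length": c.length,
                "type": c.kind,
            }
            for c in indels
        ],
        columns=INDEL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_indel_vcf(indels: Sequence[IndelCall], path: str) -> None:
    """Write a minimal VCF: placeholder 'N' sequences encode the length, the
    source sample travels in INFO, positions are 1-based."""
    chroms = sorted({c.chrom for c in indels})
    max_pos = {c: 0 for c in chroms}
    for call in indels:
        max_pos[call.chrom] = max(max_pos[call.chrom], call.start + call.length + 2)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Source exome sample">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={max_pos[c]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, call in enumerate(
            sorted(indels, key=lambda c: (c.chrom, c.start, c.sample))
        ):
            pos = call.start + 1  # VCF is 1-based
            if call.kind == "deletion":
                ref, alt = "N" * (call.length + 1), "N"
            else:
                ref, alt = "N", "N" * (call.length + 1)
            fh.write(
                f"{call.chrom}\t{pos}\t{f'indel_{i + 1}'}\t{ref}\t{alt}\t.\t.\t"
                f"SAMPLE={call.sample}\n"
            )


def read_indel_vcf(path: str) -> list[IndelCall]:
    """Read indels from a VCF; only CHROM/POS/REF/ALT (+INFO SAMPLE) are
    consumed, multi-allelic records are split, SNV records skipped."""
    out: list[IndelCall] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sample = str(rec.info.get("SAMPLE", ""))
            for alt in rec.alts or ():
                length = abs(len(rec.ref) - len(alt))
                if length < 1:
                    continue
                kind = "deletion" if len(rec.ref) > len(alt) else "insertion"
                out.append(IndelCall(sample, rec.chrom, rec.pos - 1, length, kind))
    return out


# ---------------------------------------------------------------------------
# generic TSV round trips
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
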