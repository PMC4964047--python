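"""Readers/writers for the formats the pipeline consumes.

VCFv4.2 (1-based; converted to the package's 0-based half-open
convention at this boundary, read through cyvcf2), BED (0-based
half-open), FASTA (Biopython), JASPAR-style PFMs (Bio.motifs) and TSVs
with a header row.  TSV floats are written with a fixed format so that
re-running a pipeline on identical inputs is byte-identical.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .haplotypes import HaplotypeMatrix
from .motifs import PWM

__all__ = [
    "write_vcf",
    "read_vcf_haplotypes",
    "read_vcf_table",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_pfms",
    "write_pfms",
    "write_tsv",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=balnoise
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path, records: pd.DataFrame, haplotypes: np.ndarray, sample_ids=None) -> None:
    """Write phased diploid genotypes as uncompressed VCFv4.2.

    ``records``: one row per variant with ``chrom``, ``pos`` (0-based),
    ``snp_id``, ``ref``, ``alt``.  ``haplotypes``: (2*n_ind) x S allele
    matrix, consecutive pairs forming individuals.
    """
    hap = np.asarray(haplotypes)
    n_ind = hap.shape[0] // 2
    if sample_ids is None:
        sample_ids = [f"ind{i:03d}" for i in range(n_ind)]
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in pd.unique(records["chrom"])
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER + contigs)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, row in enumerate(records.itertuples()):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(n_ind)
            )
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf_table(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a VCF into (variant table, phased haplotype matrix).

    Positions come back 0-based; the haplotype matrix is (2*n_ind) x S.
    """
    rows, columns = [], []
    for var in VCF(str(path)):
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS - 1,
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
            }
        )
        gt = np.asarray(var.genotype.array())[:, :2]
        columns.append(gt.reshape(-1))
    table = pd.DataFrame(rows)
    hap = np.array(columns, dtype=np.int8).T if columns else np.empty((0, 0), np.int8)
    return table, hap


def read_vcf_haplotypes(
    path, chrom: str, start: int | None = None, end: int | None = None
) -> HaplotypeMatrix:
    """Phased haplotypes of one chromosome (optionally a sub-window)."""
    table, hap = read_vcf_table(path)
    sel = table["chrom"] == chrom
    if start is not None:
        sel &= table["pos"] >= start
    if end is not None:
        sel &= table["pos"] < end
    idx = np.flatnonzero(sel.to_numpy())
    return HaplotypeMatrix(
        hap[:, idx], table.loc[sel, "pos"].to_numpy(), chrom=chrom
    )


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(path, intervals: pd.DataFrame) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pfms(path, pseudocount: float = 0.25) -> list[PWM]:
    """Parse JASPAR-format PFMs into scanning-ready PWMs."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PWM(counts, name=m.name or m.matrix_id, pseudocount=pseudocount))
    return out


def write_pfms(path, pfms: dict[str, np.ndarray]) -> None:
    """Write count matrices (name -> 4 x width, ACGT rows) in JASPAR format."""
    with open(path, "w") as fh:
        for name, counts in pfms.items():
            counts = np.asarray(counts)
            fh.write(f">{name}\t{name}\n")
            for base, row in zip("ACGT", counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def write_tsv(path, df: pd.DataFrame, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
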