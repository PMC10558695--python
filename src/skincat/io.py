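"""File-format boundaries: FASTA, GFF3 gene models, and TSV tables.

Internal coordinates are 0-based half-open; GFF3 on disk is 1-based
inclusive.  FASTA goes through Biopython and is wrapped at 60 columns.
Writers emit deterministic output (sorted where order is not meaningful,
fixed float formatting) so pipeline reruns are byte-identical.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_qc import GeneRecord, GenomeBin

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "write_bin",
    "read_bin",
    "read_coverage",
    "write_coverage",
    "read_pileup",
    "write_pileup",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


_GFF_ATTRS = (("marker_id", "marker_id"), ("ko", "KO"), ("cog", "COG"))


def write_gff3(genes: list[GeneRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
            attrs = [f"ID={g.gene_id}"]
            for field, key in _GFF_ATTRS:
                val = getattr(g, field)
                if val is not None:
                    attrs.append(f"{key}={val}")
            fh.write(
                "\t".join([
                    g.contig, "skincat", "CDS",
                    str(g.start + 1), str(g.end), ".", g.strand, "0",
                    ";".join(attrs),
                ]) + "\n"
            )


def read_gff3(path: str | os.PathLike) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                item.split("=", 1) for item in cols[8].split(";") if "=" in item
            )
            genes.append(GeneRecord(
                gene_id=attrs.get("ID", f"{cols[0]}:{cols[3]}"),
                contig=cols[0],
                start=int(cols[3]) - 1,
                end=int(cols[4]),
                strand=cols[6],
                marker_id=attrs.get("marker_id"),
                ko=attrs.get("KO"),
                cog=attrs.get("COG"),
            ))
    return genes


def write_bin(bin_: GenomeBin, outdir: str | os.PathLike) -> tuple[Path, Path]:
    """Write one bin as <bin_id>.fna + <bin_id>.gff3; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fna = outdir / f"{bin_.bin_id}.fna"
    gff = outdir / f"{bin_.bin_id}.gff3"
    write_fasta(dict(sorted(bin_.contigs.items())), fna)
    write_gff3(bin_.genes, gff)
    return fna, gff


def read_bin(bin_id: str, indir: str | os.PathLike,
             taxon: str | None = None) -> GenomeBin:
    indir = Path(indir)
    contigs = read_fasta(indir / f"{bin_id}.fna")
    genes = read_gff3(indir / f"{bin_id}.gff3")
    return GenomeBin(bin_id=bin_id, contigs=contigs, genes=genes, taxon=taxon)


def read_coverage(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    required = {"contig_id", "sample_id", "depth"}
    if not required.issubset(df.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    return df


def write_coverage(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.sort_values(["sample_id", "contig_id"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_pileup(path: str | os.PathLike) -> pd.DataFrame:
    """Pileup TSV: contig_id, pos (1-based), ref, A, C, G, T counts."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "ref": str})
    required = {"contig_id", "pos", "ref", "A", "C", "G", "T"}
    if not required.issubset(df.columns):
        raise ValueError(f"pileup table needs columns {sorted(required)}")
    return df


def write_pileup(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
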