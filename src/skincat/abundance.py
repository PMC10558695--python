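"""Coverage-based relative abundance and read classification rate.

Within each sample, contig relative abundance is the contig's depth divided
by the summed depth of all contigs in that sample (scale-invariant, sums to
1 for non-empty samples).  Species abundance is the median of the relative
abundances of the species' contigs — robust to dropped or contaminating
contigs.  The classification rate emulates the fraction of reads a mapper
assigns to the catalog: a read is classified when at least 60% of its
k-mers (k = 31) occur in the representative-genome k-mer index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome_qc import GenomeBin
from .seqcore import kmer_set, reverse_complement

__all__ = [
    "normalize_depths",
    "species_abundance",
    "classification_rate",
]


def normalize_depths(cov: pd.DataFrame) -> pd.DataFrame:
    """Add per-sample relative abundance to a coverage table.

    Input columns: contig_id, sample_id, depth.  Output adds
    ``rel_abundance`` (depth / per-sample total; all zero for all-zero
    samples, which are flagged in the ``empty_sample`` column).
    """
    required = {"contig_id", "sample_id", "depth"}
    if not required.issubset(cov.columns):
        raise ValueError(f"coverage table needs columns {sorted(required)}")
    if (cov["depth"] < 0).any():
        raise ValueError("depths must be non-negative")
    if cov.duplicated(["contig_id", "sample_id"]).any():
        raise ValueError("(contig, sample) pairs must be unique")
    out = cov.copy()
    totals = out.groupby("sample_id")["depth"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rel_abundance"] = np.where(totals > 0, out["depth"] / totals, 0.0)
    out["empty_sample"] = totals == 0
    return out


def species_abundance(
    normalized: pd.DataFrame,
    species_contigs: dict[str, list[str]],
    renormalize: bool = False,
) -> pd.DataFrame:
    """Median-of-contigs species abundance matrix (species x sample).

    For each species and sample, the median over its contigs' relative
    abundances (even counts use the mean of the central pair).  Medians are
    reported as-is; ``renormalize=True`` additionally rescales each sample
    to sum to 1.
    """
    contig_to_species = {}
    for sp, contigs in species_contigs.items():
        for c in contigs:
            contig_to_species[c] = sp
    df = normalized.copy()
    df["species_id"] = df["contig_id"].map(contig_to_species)
    df = df.dropna(subset=["species_id"])
    mat = (
        df.groupby(["species_id", "sample_id"])["rel_abundance"]
        .median()
        .unstack(fill_value=0.0)
        .sort_index()
    )
    mat = mat.reindex(sorted(species_contigs), fill_value=0.0)
    if renormalize:
        totals = mat.sum(axis=0)
        mat = mat.div(totals.where(totals > 0, 1.0), axis=1)
    return mat


def classification_rate(
    reads: list[str],
    representatives: list[GenomeBin],
    k: int = 31,
    min_containment: float = 0.6,
) -> float:
    """Fraction of reads whose k-mer containment in the catalog >= threshold.

    Both strands of the catalog are indexed; a read shorter than k is
    unclassified.
    """
    if not reads:
        raise ValueError("read set is empty")
    catalog: set[str] = set()
    for rep in representatives:
        for seq in rep.contigs.values():
            catalog |= kmer_set(seq.upper(), k)
            catalog |= kmer_set(reverse_complement(seq.upper()), k)
    classified = 0
    for read in reads:
        kmers = kmer_set(read.upper(), k)
        if not kmers:
            continue
        hits = sum(1 for km in kmers if km in catalog)
        if hits / len(kmers) >= min_containment:
            classified += 1
    return classified / len(reads)
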