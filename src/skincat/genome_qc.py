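"""Genome-bin containers and marker-based quality tiering.

Completeness and contamination are estimated from a set of expected
single-copy marker loci tagged in the gene models (attribute ``marker_id``):

* completeness   = distinct markers present / markers expected
* contamination  = surplus marker copies / markers expected

Bins are tiered with the conventional MAG thresholds: high quality (HQ) at
completeness >= 90% and contamination <= 5%; medium quality (MQ) at
completeness >= 50% and contamination <= 10%; everything else fails.  Both
boundaries are inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from . import seqcore

__all__ = [
    "GeneRecord",
    "GenomeBin",
    "MarkerSet",
    "estimate_quality",
    "classify_tier",
    "qc_report",
    "HQ_COMPLETENESS",
    "HQ_CONTAMINATION",
    "MQ_COMPLETENESS",
    "MQ_CONTAMINATION",
]

HQ_COMPLETENESS = 0.90
HQ_CONTAMINATION = 0.05
MQ_COMPLETENESS = 0.50
MQ_CONTAMINATION = 0.10


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene on a contig (0-based half-open coordinates)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    marker_id: str | None = None
    ko: str | None = None
    cog: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeBin:
    """A set of contigs with gene models, quality estimates and a taxon label."""

    bin_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    completeness: float | None = None
    contamination: float | None = None
    tier: str | None = None
    taxon: str | None = None
    source_sample: str | None = None

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(f"gene {g.gene_id} exceeds contig bounds")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Coding-strand DNA of a gene (reverse-complemented for '-')."""
        raw = self.contigs[gene.contig][gene.start : gene.end]
        return seqcore.reverse_complement(raw) if gene.strand == "-" else raw

    def protein(self, gene: GeneRecord) -> str:
        """Translated product, trailing stop removed."""
        aa = seqcore.translate(self.contigs[gene.contig][gene.start : gene.end],
                               gene.strand)
        return aa[:-1] if aa.endswith("*") else aa

    def genes_by_contig(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {c: [] for c in self.contigs}
        for g in self.genes:
            out[g.contig].append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.start)
        return out


@dataclass(frozen=True)
class MarkerSet:
    """Expected single-copy marker loci."""

    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("marker set must be non-empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids must be unique")

    def __len__(self) -> int:
        return len(self.marker_ids)


def estimate_quality(bin_: GenomeBin, markers: MarkerSet) -> tuple[float, float]:
    """Marker-count completeness and contamination of a bin.

    Returns ``(completeness, contamination)`` where completeness is the
    fraction of expected markers observed at least once and contamination
    is the summed surplus copy count divided by the marker-set size.
    """
    expected = set(markers.marker_ids)
    counts = Counter(
        g.marker_id for g in bin_.genes
        if g.marker_id is not None and g.marker_id in expected
    )
    completeness = len(counts) / len(markers)
    contamination = sum(c - 1 for c in counts.values() if c > 1) / len(markers)
    return completeness, contamination


def classify_tier(completeness: float, contamination: float) -> str:
    """HQ / MQ / FAIL tier from the two quality scalars (inclusive bounds)."""
    if completeness >= HQ_COMPLETENESS and contamination <= HQ_CONTAMINATION:
        return "HQ"
    if completeness >= MQ_COMPLETENESS and contamination <= MQ_CONTAMINATION:
        return "MQ"
    return "FAIL"


def qc_report(bins: list[GenomeBin], markers: MarkerSet) -> list[GenomeBin]:
    """Annotate each bin with quality estimates and tier (returns new bins)."""
    out = []
    for b in bins:
        comp, cont = estimate_quality(b, markers)
        out.append(replace_quality(b, comp, cont))
    return out


def replace_quality(b: GenomeBin, comp: float, cont: float) -> GenomeBin:
    new = GenomeBin(
        bin_id=b.bin_id,
        contigs=b.contigs,
        genes=b.genes,
        completeness=comp,
        contamination=cont,
        tier=classify_tier(comp, cont),
        taxon=b.taxon,
        source_sample=b.source_sample,
    )
    return new
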