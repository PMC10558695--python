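"""Shared-gene networks over biosynthetic gene clusters (BGCs).

Two clusters share a gene when a protein of one aligns to a protein of the
other covering at least 50% of the query with amino-acid identity strictly
above 50% (each query gene pairs with at most its best hit).  Query
coverage is directional, so the unordered pair is considered shared if the
criterion holds in either direction.  Edges connect clusters with at least
one shared gene, weighted by the mean identity of the shared pairs;
connected components are the subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import seqcore

__all__ = [
    "BGCRecord",
    "BGCNetwork",
    "shared_proteins",
    "build_network",
    "subnet_summary",
]

MIN_QUERY_COVERAGE = 0.50  # inclusive
MIN_IDENTITY = 0.50        # strict


@dataclass
class BGCRecord:
    """One biosynthetic gene cluster: its genome, class and protein genes."""

    bgc_id: str
    genome_id: str
    product_class: str
    genes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"BGC {self.bgc_id} must carry at least one gene")


@dataclass
class BGCNetwork:
    graph: nx.Graph
    components: list[set[str]] = field(default_factory=list)


def shared_proteins(
    a: BGCRecord,
    b: BGCRecord,
    min_cov: float = MIN_QUERY_COVERAGE,
    min_id: float = MIN_IDENTITY,
) -> list[tuple[str, str, float]]:
    """Best-hit shared gene pairs from ``a`` (query side) into ``b``.

    A pair is shared iff the alignment covers >= ``min_cov`` of the query
    gene and identity > ``min_id`` (strict).  Returns
    (query_gene, subject_gene, identity) triples.
    """
    pairs = []
    for qid in sorted(a.genes):
        qseq = a.genes[qid]
        best = None
        for sid in sorted(b.genes):
            aln = seqcore.align_pair(qseq, b.genes[sid], mode="local",
                                     alphabet="protein")
            if aln is None:
                continue
            if aln.query_coverage >= min_cov and aln.identity > min_id:
                cand = (-aln.score, sid, aln.identity)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            pairs.append((qid, best[1], best[2]))
    return pairs


def build_network(
    bgcs: list[BGCRecord],
    min_shared: int = 1,
    min_cov: float = MIN_QUERY_COVERAGE,
    min_id: float = MIN_IDENTITY,
) -> BGCNetwork:
    """Shared-gene graph over clusters, symmetrized over query direction.

    The shared-gene count of an unordered pair is the number of unordered
    gene pairs satisfying the criterion in either direction; an edge is
    drawn at >= ``min_shared`` shared genes with the mean identity as
    weight.  Components (including singletons) partition the node set.
    """
    ids = [b.bgc_id for b in bgcs]
    if len(set(ids)) != len(ids):
        raise ValueError("bgc ids must be unique")
    graph = nx.Graph()
    for b in sorted(bgcs, key=lambda x: x.bgc_id):
        graph.add_node(b.bgc_id, genome_id=b.genome_id,
                       product_class=b.product_class)
    ordered = sorted(bgcs, key=lambda x: x.bgc_id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            pairs: dict[frozenset, float] = {}
            for q, s, ident in shared_proteins(a, b, min_cov, min_id):
                key = frozenset((q, s))
                pairs[key] = max(pairs.get(key, 0.0), ident)
            for q, s, ident in shared_proteins(b, a, min_cov, min_id):
                key = frozenset((q, s))
                pairs[key] = max(pairs.get(key, 0.0), ident)
            if len(pairs) >= min_shared:
                graph.add_edge(
                    a.bgc_id, b.bgc_id,
                    shared_gene_count=len(pairs),
                    mean_identity=sum(pairs.values()) / len(pairs))
    components = [set(c) for c in sorted(
        nx.connected_components(graph), key=lambda c: sorted(c)[0])]
    return BGCNetwork(graph=graph, components=components)


def subnet_summary(
    network: BGCNetwork,
    bgcs: list[BGCRecord],
    genome_taxa: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per connected component: size, product classes, taxa spanned."""
    by_id = {b.bgc_id: b for b in bgcs}
    rows = []
    for ci, comp in enumerate(network.components, start=1):
        members = sorted(comp)
        classes = sorted({by_id[m].product_class for m in members})
        genomes = sorted({by_id[m].genome_id for m in members})
        taxa = sorted({genome_taxa[g] for g in genomes
                       if genome_taxa and g in genome_taxa}) if genome_taxa else []
        rows.append({
            "component_id": f"subnet{ci}",
            "size": len(members),
            "members": ",".join(members),
            "product_classes": ",".join(classes),
            "genomes": ",".join(genomes),
            "taxa_spanned": ",".join(taxa),
        })
    return pd.DataFrame(rows, columns=[
        "component_id", "size", "members", "product_classes",
        "genomes", "taxa_spanned"])
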