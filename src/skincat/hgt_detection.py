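"""Horizontal gene transfer detection with a recency split.

Candidates come from a best-match screen: a gene is flagged when its best
hit across taxon groups (at the chosen rank of the taxon label) is both
strong (identity >= 0.9 by default) and stronger than any within-group hit
— the signature of a gene that is more similar to a foreign lineage than
to its own.  Symmetric detections of the same donor/recipient gene pair
are merged into one event.  Orientation follows group support: the side
whose group-mates also carry close homologs of the gene is the donor
(vertical inheritance leaves homologs among relatives); with equal support
the orientation is marked ambiguous.

Candidates can additionally be screened for phylogenetic incongruence: the
gene's neighbor-joining tree is compared with the genome (species) tree,
and a candidate is validated when the recipient's gene sits topologically
closer to the donor group than the species tree predicts.

Recency: events with divergence (1 - nucleotide identity of the
donor/recipient gene alignment) strictly below 1% are "recent".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as scistats

from . import seqcore
from .genome_qc import GenomeBin

__all__ = [
    "HGTEvent",
    "detect_candidates",
    "validate_phylogeny",
    "classify_recency",
    "cog_contrast",
    "RECENCY_THRESHOLD",
]

RECENCY_THRESHOLD = 0.01


@dataclass
class HGTEvent:
    gene_id: str
    donor_genome: str
    recipient_genome: str
    donor_taxon: str
    recipient_taxon: str
    identity: float
    divergence: float
    recency: str
    cog_category: str | None = None
    orientation: str = "resolved"  # resolved | ambiguous
    validation: str = "unvalidated"  # unvalidated | validated | rejected
    donor_gene_id: str | None = None


def classify_recency(divergence: float, threshold: float = RECENCY_THRESHOLD) -> str:
    """"recent" iff divergence is strictly below the threshold."""
    return "recent" if divergence < threshold else "non_recent"


def _taxon_group(bin_: GenomeBin, rank: int) -> str:
    if not bin_.taxon:
        raise ValueError(f"bin {bin_.bin_id} lacks a taxon label")
    parts = bin_.taxon.split(";")
    return parts[min(rank, len(parts) - 1)]


def _gene_table(bins: list[GenomeBin], rank: int):
    """(gene_key -> (bin_id, group, gene, dna, kmers)) over all genes."""
    table = {}
    for b in sorted(bins, key=lambda x: x.bin_id):
        group = _taxon_group(b, rank)
        for g in b.genes:
            if g.marker_id is not None:
                continue
            dna = b.gene_sequence(g)
            table[(b.bin_id, g.gene_id)] = (
                b.bin_id, group, g, dna,
                seqcore.kmer_set(dna, seqcore.DNA_SEED_K))
    return table


MIN_HIT_COVERAGE = 0.5


def _best_hit(dna: str, kmers: set[str], candidates,
              min_cov: float = MIN_HIT_COVERAGE) -> tuple[float, tuple | None]:
    """Highest-identity alignment of a gene against candidate genes.

    Hits must span at least ``min_cov`` of the query gene; without the
    coverage floor, chance seed k-mers between unrelated genes yield short
    perfect local alignments that masquerade as strong hits.
    """
    best_id = 0.0
    best = None
    for entry in candidates:
        _, _, _, other_dna, other_kmers = entry
        if not (kmers & other_kmers):
            continue
        aln = seqcore.align_pair(dna, other_dna, mode="local", alphabet="dna")
        if aln is None or aln.query_coverage < min_cov:
            continue
        if aln.identity > best_id:
            best_id = aln.identity
            best = entry
    return best_id, best


def detect_candidates(
    bins: list[GenomeBin],
    rank: int = 0,
    min_identity: float = 0.9,
) -> list[HGTEvent]:
    """Best-match HGT candidates between taxon groups at the given rank."""
    groups = {_taxon_group(b, rank) for b in bins}
    if len(groups) < 2:
        raise ValueError("need at least two taxon groups for HGT detection")
    table = _gene_table(bins, rank)
    entries = list(table.values())
    raw: dict[frozenset, dict] = {}
    for bin_id, group, gene, dna, kmers in entries:
        cross = [e for e in entries if e[1] != group]
        within = [e for e in entries if e[1] == group and e[0] != bin_id]
        cross_id, cross_best = _best_hit(dna, kmers, cross)
        if cross_best is None or cross_id < min_identity:
            continue
        within_id, _ = _best_hit(dna, kmers, within)
        if within_id >= cross_id:
            continue
        other_bin, other_group, other_gene, _, _ = cross_best
        key = frozenset(((bin_id, gene.gene_id),
                         (other_bin, other_gene.gene_id)))
        if key in raw:
            continue
        raw[key] = {
            "a": (bin_id, group, gene),
            "b": (other_bin, other_group, other_gene),
            "identity": cross_id,
        }
    events = []
    for key in sorted(raw, key=lambda k: sorted(k)):
        rec = raw[key]
        a_bin, a_group, a_gene = rec["a"]
        b_bin, b_group, b_gene = rec["b"]
        a_support = _group_support(table, a_bin, a_group, a_gene, min_identity)
        b_support = _group_support(table, b_bin, b_group, b_gene, min_identity)
        if a_support > b_support:
            donor, recipient = rec["a"], rec["b"]
            orientation = "resolved"
        elif b_support > a_support:
            donor, recipient = rec["b"], rec["a"]
            orientation = "resolved"
        else:
            donor, recipient = sorted(
                [rec["a"], rec["b"]], key=lambda x: x[0])
            orientation = "ambiguous"
        divergence = 1.0 - rec["identity"]
        events.append(HGTEvent(
            gene_id=recipient[2].gene_id,
            donor_genome=donor[0],
            recipient_genome=recipient[0],
            donor_taxon=donor[1],
            recipient_taxon=recipient[1],
            identity=rec["identity"],
            divergence=divergence,
            recency=classify_recency(divergence),
            cog_category=recipient[2].cog,
            orientation=orientation,
            donor_gene_id=donor[2].gene_id,
        ))
    return events


def _group_support(table, bin_id: str, group: str, gene, min_identity: float) -> int:
    """Number of group-mates (other genomes, same group) carrying a close
    homolog of the gene."""
    entry = table[(bin_id, gene.gene_id)]
    _, _, _, dna, kmers = entry
    support_bins = set()
    for other in table.values():
        o_bin, o_group = other[0], other[1]
        if o_group != group or o_bin == bin_id:
            continue
        if not (kmers & other[4]):
            continue
        aln = seqcore.align_pair(dna, other[3], mode="local", alphabet="dna")
        if (aln is not None and aln.query_coverage >= MIN_HIT_COVERAGE
                and aln.identity >= min_identity):
            support_bins.add(o_bin)
    return len(support_bins)


def _nj_tree(labels: list[str], dm: np.ndarray):
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(dm, ids=labels))


def _topo_distance(tree, a: str, b: str) -> int:
    """Number of internal edges between two tips."""
    ta = tree.find(a)
    tb = tree.find(b)
    return int(ta.distance(tb, use_length=False))


def validate_phylogeny(
    event: HGTEvent,
    bins: list[GenomeBin],
    ani_distances: dict[frozenset, float] | None = None,
    rank: int = 0,
) -> HGTEvent:
    """Phylogenetic-incongruence screen for one candidate event.

    Builds the genome (species) tree by neighbor joining on (1 - ANI)
    distances over *all* genomes (unaligned pairs at distance 1) and the
    candidate gene's tree over the genomes carrying a homolog, from
    best-homolog protein distances.  The event is validated when, by edge
    count, the recipient's gene sits closer to a donor-group carrier than
    to any carrier of its own group, and no farther from the donor group
    than the full genome tree predicts — a transferred gene nests inside
    the donor clade, while a vertically inherited family keeps the
    recipient with its own relatives.  With fewer than four homolog
    carriers or four genomes the comparison is degenerate and the event
    passes as "unvalidated".
    """
    by_id = {b.bin_id: b for b in bins}
    recipient = by_id[event.recipient_genome]
    gene = next(g for g in recipient.genes if g.gene_id == event.gene_id)
    query = recipient.protein(gene)
    qk = seqcore.kmer_set(query, seqcore.PROTEIN_SEED_K)
    homologs: dict[str, str] = {event.recipient_genome: query}
    for b in sorted(bins, key=lambda x: x.bin_id):
        if b.bin_id == event.recipient_genome:
            continue
        best_id, best_seq = 0.0, None
        for g in b.genes:
            if g.marker_id is not None:
                continue
            prot = b.protein(g)
            if not (qk & seqcore.kmer_set(prot, seqcore.PROTEIN_SEED_K)):
                continue
            aln = seqcore.align_pair(query, prot, mode="local", alphabet="protein")
            if aln is None or aln.query_coverage < MIN_HIT_COVERAGE:
                continue
            if aln.identity > best_id:
                best_id, best_seq = aln.identity, prot
        if best_seq is not None and best_id >= 0.5:
            homologs[b.bin_id] = best_seq
    all_labels = sorted(by_id)
    if len(homologs) < 4 or len(all_labels) < 4 \
            or event.donor_genome not in homologs:
        return replace(event, validation="unvalidated")

    labels = sorted(homologs)
    n = len(labels)
    gene_dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = seqcore.align_pair(homologs[labels[i]], homologs[labels[j]],
                                 mode="local", alphabet="protein")
        d = 1.0 - aln.identity if aln is not None else 1.0
        gene_dm[i, j] = gene_dm[j, i] = d
    gene_tree = _nj_tree(labels, gene_dm)

    if ani_distances is None:
        ani_distances = {}
    from .dereplication import compute_ani
    for a, b in itertools.combinations(all_labels, 2):
        key = frozenset((a, b))
        if key not in ani_distances:
            res = compute_ani(by_id[a], by_id[b])
            ani_distances[key] = 1.0 - res.ani if res.af > 0 else 1.0
    m = len(all_labels)
    sp_dm = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        sp_dm[i, j] = sp_dm[j, i] = ani_distances[
            frozenset((all_labels[i], all_labels[j]))]
    species_tree = _nj_tree(all_labels, sp_dm)

    donor_group = {b.bin_id for b in bins
                   if _taxon_group(b, rank) == event.donor_taxon
                   and b.bin_id in homologs
                   and b.bin_id != event.recipient_genome}
    own_group = {b.bin_id for b in bins
                 if _taxon_group(b, rank) == event.recipient_taxon
                 and b.bin_id in homologs
                 and b.bin_id != event.recipient_genome}
    if not donor_group:
        return replace(event, validation="unvalidated")
    donor_gene_d = min(_topo_distance(gene_tree, event.recipient_genome, d)
                       for d in donor_group)
    own_gene_d = (min(_topo_distance(gene_tree, event.recipient_genome, d)
                      for d in own_group) if own_group else np.inf)
    sp_d = min(_topo_distance(species_tree, event.recipient_genome, d)
               for d in donor_group)
    # transferred genes nest with the donor clade, away from the
    # recipient's own relatives, and no farther than the genome tree
    # places the recipient from the donor group
    status = ("validated"
              if donor_gene_d < own_gene_d and donor_gene_d <= sp_d
              else "rejected")
    return replace(event, validation=status)


def cog_contrast(events: list[HGTEvent]) -> pd.DataFrame:
    """Fisher-exact COG enrichment of recent vs non-recent events.

    One 2x2 table per COG letter observed among the events
    (recent/non-recent x in-category/not), two-sided p with
    Benjamini-Hochberg q, sorted by q then letter.
    """
    labelled = [e for e in events if e.cog_category]
    letters = sorted({e.cog_category for e in labelled})
    n_recent = sum(1 for e in labelled if e.recency == "recent")
    n_nonrec = len(labelled) - n_recent
    rows = []
    for letter in letters:
        r_in = sum(1 for e in labelled
                   if e.recency == "recent" and e.cog_category == letter)
        nr_in = sum(1 for e in labelled
                    if e.recency == "non_recent" and e.cog_category == letter)
        table = [[r_in, n_recent - r_in], [nr_in, n_nonrec - nr_in]]
        odds, p = scistats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "cog_category": letter,
            "recent_in": r_in,
            "recent_out": n_recent - r_in,
            "nonrecent_in": nr_in,
            "nonrecent_out": n_nonrec - nr_in,
            "odds_ratio": odds,
            "p_value": p,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = scistats.false_discovery_control(
            df["p_value"].to_numpy(), method="bh")
        df = df.sort_values(["q_value", "cog_category"]).reset_index(drop=True)
    return df
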