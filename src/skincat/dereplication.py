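"""ANI-based species dereplication and representative selection.

Pairwise average nucleotide identity (ANI) follows the fragment scheme:
the smaller genome is cut into ~1 kb fragments, each fragment is aligned
glocally against the other genome (seed k-mer prefilter, then banded
extension), and fragments mapping at >= 80% identity and >= 90% coverage
enter the ANI mean.  Alignment fraction (AF) is the mapped fraction of the
smaller genome.  Species clusters are formed greedily at the standard
thresholds ANI >= 95% and AF >= 30%, seeding each cluster with the best
remaining bin by quality; the representative is chosen lexicographically by
(minimal contamination, maximal completeness, maximal length, smallest id).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import seqcore
from .genome_qc import GenomeBin

__all__ = [
    "ANIResult",
    "SpeciesCluster",
    "compute_ani",
    "cluster_genomes",
    "select_representative",
    "quality_rank_key",
]

FRAGMENT_MAP_MIN_IDENTITY = 0.8
FRAGMENT_MAP_MIN_COVERAGE = 0.9


@dataclass(frozen=True)
class ANIResult:
    """Symmetric ANI/AF record for an unordered genome pair."""

    genome_a: str
    genome_b: str
    ani: float
    af: float

    @property
    def pair(self) -> frozenset:
        return frozenset((self.genome_a, self.genome_b))


@dataclass
class SpeciesCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str


def _fragments(seq: str, fragment_length: int) -> list[str]:
    """Cut a contig into fragments; the last fragment absorbs the remainder
    so every base is covered (short contigs become single fragments)."""
    if len(seq) <= fragment_length:
        return [seq]
    n = len(seq) // fragment_length
    frags = [seq[i * fragment_length : (i + 1) * fragment_length] for i in range(n - 1)]
    frags.append(seq[(n - 1) * fragment_length :])
    return frags


class _SubjectIndex:
    """Concatenated-genome seed index reused across fragments."""

    def __init__(self, genome: GenomeBin, k: int = seqcore.DNA_SEED_K):
        parts = []
        for name in sorted(genome.contigs):
            parts.append(genome.contigs[name].upper())
        self.seq = ("N" * 50).join(parts)
        self.k = k
        self.positions: dict[str, list[int]] = {}
        for j in range(len(self.seq) - k + 1):
            self.positions.setdefault(self.seq[j : j + k], []).append(j)

    def window(self, query: str) -> tuple[int, int] | None:
        diag_hits: dict[int, int] = {}
        k = self.k
        seen = False
        for i in range(len(query) - k + 1):
            hits = self.positions.get(query[i : i + k])
            if hits:
                seen = True
                for j in hits:
                    d = j - i
                    diag_hits[d] = diag_hits.get(d, 0) + 1
        if not seen:
            return None
        best = max(diag_hits, key=lambda d: (diag_hits[d], -abs(d)))
        lo = max(0, best - seqcore.BAND_WIDTH)
        hi = min(len(self.seq), best + len(query) + seqcore.BAND_WIDTH)
        return lo, hi


def compute_ani(
    a: GenomeBin,
    b: GenomeBin,
    fragment_length: int = 1000,
    _subject_index: "_SubjectIndex | None" = None,
) -> ANIResult:
    """Fragment-based ANI and alignment fraction between two genomes.

    The smaller genome donates fragments; AF is length-weighted mapped
    fraction of that genome, capped at 1.
    """
    if not a.contigs or not b.contigs:
        raise ValueError("both genomes must be non-empty")
    small, big = (a, b) if a.total_length <= b.total_length else (b, a)
    if fragment_length > small.total_length:
        raise ValueError(
            f"fragment_length {fragment_length} exceeds smaller genome "
            f"({small.total_length} nt)")
    index = _subject_index if _subject_index is not None else _SubjectIndex(big)
    aligner = seqcore._make_aligner("glocal", "dna")
    mapped_len = 0
    identities = []
    weights = []
    for contig in sorted(small.contigs):
        for frag in _fragments(small.contigs[contig].upper(), fragment_length):
            win = index.window(frag)
            if win is None:
                continue
            lo, hi = win
            aln = aligner.align(frag, index.seq[lo:hi])[0]
            summary = seqcore._summarize(aln, frag, index.seq[lo:hi], lo,
                                         "frag", big.bin_id)
            if (summary.identity >= FRAGMENT_MAP_MIN_IDENTITY
                    and summary.query_coverage >= FRAGMENT_MAP_MIN_COVERAGE):
                identities.append(summary.identity)
                weights.append(len(frag))
                mapped_len += len(frag)
    if not identities:
        return ANIResult(a.bin_id, b.bin_id, ani=0.0, af=0.0)
    ani = sum(i * w for i, w in zip(identities, weights)) / sum(weights)
    af = min(1.0, mapped_len / small.total_length)
    return ANIResult(a.bin_id, b.bin_id, ani=ani, af=af)


def quality_rank_key(bin_: GenomeBin) -> tuple:
    """Sort key implementing the representative preference order:
    minimal contamination, then maximal completeness, then maximal total
    length, then lexicographically smallest id."""
    return (
        bin_.contamination if bin_.contamination is not None else 1.0,
        -(bin_.completeness if bin_.completeness is not None else 0.0),
        -bin_.total_length,
        bin_.bin_id,
    )


def cluster_genomes(
    bins: list[GenomeBin],
    ani_threshold: float = 0.95,
    af_threshold: float = 0.30,
    fragment_length: int = 1000,
    ani_cache: dict[frozenset, ANIResult] | None = None,
) -> list[SpeciesCluster]:
    """Greedy species clustering at the ANI/AF thresholds.

    Bins are ranked by quality; the best unassigned bin seeds a cluster and
    collects every unassigned bin at ANI >= threshold and AF >= threshold
    against it.  The seed (best-quality member) is the representative.
    Pairwise ANI is computed on demand and optionally cached.
    """
    for b in bins:
        if b.completeness is None or b.contamination is None:
            raise ValueError(f"bin {b.bin_id} lacks quality estimates")
    cache = ani_cache if ani_cache is not None else {}
    ordered = sorted(bins, key=quality_rank_key)
    unassigned = list(ordered)
    clusters: list[SpeciesCluster] = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [seed.bin_id]
        index = _SubjectIndex(seed) if unassigned else None
        remaining = []
        for other in unassigned:
            key = frozenset((seed.bin_id, other.bin_id))
            res = cache.get(key)
            if res is None:
                if other.total_length <= seed.total_length:
                    res = compute_ani(other, seed, fragment_length,
                                      _subject_index=index)
                else:
                    res = compute_ani(other, seed, fragment_length)
                cache[key] = res
            if res.ani >= ani_threshold and res.af >= af_threshold:
                members.append(other.bin_id)
            else:
                remaining.append(other)
        unassigned = remaining
        clusters.append(SpeciesCluster(
            cluster_id=f"cluster{len(clusters) + 1}",
            member_ids=members,
            representative_id=seed.bin_id,
        ))
    return clusters


def select_representative(
    cluster: SpeciesCluster,
    bins_by_id: dict[str, GenomeBin],
) -> str:
    """Best member by (min contamination, max completeness, max length, id)."""
    members = [bins_by_id[m] for m in cluster.member_ids]
    return min(members, key=quality_rank_key).bin_id
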