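"""Shared sequence primitives: k-mer seeded pairwise alignment and translation.

All downstream stages (ANI, protein families, HGT, BGC sharing, SNV codon
classification) sit on the two operations here:

* :func:`align_pair` — a seed-and-extend pairwise aligner.  Sequences must
  share an exact k-mer (k = 15 for DNA, 5 for protein) to be considered
  alignable at all; extension runs dynamic programming (Biopython's
  ``PairwiseAligner``) on a diagonal window around the densest seed
  diagonal.  ``local`` is Smith-Waterman-style; ``glocal`` aligns the whole
  query against a substring of the subject (the mode fragment-based ANI
  needs).
* :func:`translate` — bacterial (translation table 11) codon translation
  with strand resolution; codons containing ambiguity codes become ``X``.

Coordinates are 0-based half-open everywhere in memory; 1-based inclusive
coordinates appear only at GFF3/VCF-style I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "Alignment",
    "align_pair",
    "translate",
    "reverse_complement",
    "kmer_set",
    "shared_kmers",
]

DNA_SEED_K = 15
PROTEIN_SEED_K = 5
BAND_WIDTH = 32

_DNA_ALPHABET = set("ACGTURYSWKMBDHVN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment summary.

    ``identity`` is computed over aligned columns with gap columns counted
    as mismatches; ``query_coverage`` is the aligned query span divided by
    the full query length.  Coordinates are 0-based half-open.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identity: float
    query_coverage: float
    score: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity out of [0,1]: {self.identity}")
        if not (0.0 < self.query_coverage <= 1.0):
            raise ValueError(f"query_coverage out of (0,1]: {self.query_coverage}")
        if self.query_end <= self.query_start or self.subject_end <= self.subject_start:
            raise ValueError("alignment ends must exceed starts")


def _check_alphabet(seq: str, alphabet: str, name: str) -> None:
    allowed = _DNA_ALPHABET if alphabet == "dna" else _PROTEIN_ALPHABET
    for ch in set(seq.upper()):
        if ch not in allowed:
            raise ValueError(
                f"invalid {alphabet} character {ch!r} in {name} sequence"
            )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_set(seq: str, k: int) -> set[str]:
    """All length-k substrings of ``seq`` (empty set if shorter than k)."""
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shared_kmers(a: str, b: str, k: int) -> set[str]:
    return kmer_set(a, k) & kmer_set(b, k)


@lru_cache(maxsize=8)
def _make_aligner(mode: str, alphabet: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    if alphabet == "dna":
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        # ambiguity codes score as mismatches
        aligner.wildcard = None
    else:
        matrix = substitution_matrices.load("BLOSUM62")
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    if mode == "local":
        aligner.mode = "local"
    else:  # glocal: query global, subject-end gaps free
        aligner.mode = "global"
        # subject overhang (insertions relative to the query) is free
        aligner.end_insertion_score = 0
    return aligner


def _seed_window(query: str, subject: str, k: int) -> tuple[int, int] | None:
    """Subject window around the densest shared-k-mer diagonal, or None."""
    qpos: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qpos.setdefault(query[i : i + k], []).append(i)
    diag_hits: dict[int, int] = {}
    any_seed = False
    for j in range(len(subject) - k + 1):
        kmer = subject[j : j + k]
        hits = qpos.get(kmer)
        if hits:
            any_seed = True
            for i in hits:
                d = j - i
                diag_hits[d] = diag_hits.get(d, 0) + 1
    if not any_seed:
        return None
    best_diag = max(diag_hits, key=lambda d: (diag_hits[d], -abs(d)))
    lo = max(0, best_diag - BAND_WIDTH)
    hi = min(len(subject), best_diag + len(query) + BAND_WIDTH)
    return lo, hi


def _summarize(alignment, query: str, subject: str, offset: int,
               query_id: str, subject_id: str) -> Alignment:
    blocks_q, blocks_s = alignment.aligned
    matches = 0
    aligned_cols = 0
    gap_cols = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        if prev_q is not None:
            gap_cols += (qs - prev_q) + (ss - prev_s)
        sub_q = query[qs:qe]
        sub_s = subject[ss:se]
        matches += sum(1 for x, y in zip(sub_q, sub_s) if x == y)
        aligned_cols += qe - qs
        prev_q, prev_s = qe, se
    columns = aligned_cols + gap_cols
    identity = matches / columns if columns else 0.0
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        query_start=q_start,
        query_end=q_end,
        subject_start=s_start + offset,
        subject_end=s_end + offset,
        identity=identity,
        query_coverage=(q_end - q_start) / len(query),
        score=int(alignment.score),
    )


def align_pair(
    query: str,
    subject: str,
    mode: str = "local",
    alphabet: str = "dna",
    query_id: str = "query",
    subject_id: str = "subject",
) -> Alignment | None:
    """Align ``query`` against ``subject``; None when no seed k-mer is shared.

    Parameters
    ----------
    mode : {"local", "glocal"}
        ``glocal`` forces the full query to align within the subject.
    alphabet : {"dna", "protein"}
        Selects seed length and scoring scheme (2/-3 with gap -5/-2 for
        DNA; BLOSUM62 with gap -11/-1 for protein).
    """
    if mode not in ("local", "glocal"):
        raise ValueError(f"unknown mode {mode!r}")
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    query = query.upper()
    subject = subject.upper()
    _check_alphabet(query, alphabet, "query")
    _check_alphabet(subject, alphabet, "subject")
    k = DNA_SEED_K if alphabet == "dna" else PROTEIN_SEED_K
    window = _seed_window(query, subject, k)
    if window is None:
        return None
    lo, hi = window
    sub = subject[lo:hi]
    aligner = _make_aligner(mode, alphabet)
    alignments = aligner.align(query, sub)
    best = alignments[0]
    if not len(best.aligned[0]):
        return None
    return _summarize(best, query, sub, lo, query_id, subject_id)


_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
_CODON_MAP = dict(_BACTERIAL_TABLE.forward_table)
for _stop in _BACTERIAL_TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"


def translate(cds: str, strand: str = "+") -> str:
    """Translate a CDS with bacterial code (table 11).

    ``-`` strand sequences are reverse-complemented first.  Codons with any
    ambiguity code translate to ``X``; stops to ``*``.  Length must be a
    multiple of 3.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = cds.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(_CODON_MAP.get(codon, "X"))
    return "".join(out)
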