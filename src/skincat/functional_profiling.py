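"""Nonredundant protein families and KEGG-module completeness.

Protein families are built by greedy incremental clustering in descending
length order: each protein joins the first existing family whose
representative it matches at >= 50% identity over >= 90% of the shorter
sequence, otherwise it founds a new family (the MMseqs2-style
``--min-seq-id 0.5 -c 0.9`` criterion).  Assignment of query proteins to
existing families takes the best-scoring representative at >= 30% query
coverage and an alignment score above a null-calibrated threshold (the
raw-score stand-in for a BLAST E-value cutoff; see ``DEFAULT_SCORE_THRESHOLD``).

KEGG modules are boolean expressions over KO identifiers: space-separated
top-level steps (all required), commas for alternatives, ``+`` for complex
subunits (all required), parentheses for grouping, and ``-``-prefixed
optional components (ignored).  Module completeness is the fraction of
top-level steps whose expression is satisfied by the genome's KO set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import seqcore

__all__ = [
    "ProteinFamily",
    "KEGGModuleDef",
    "cluster_proteins",
    "assign_to_families",
    "module_completeness",
    "parse_module_definition",
    "DEFAULT_SCORE_THRESHOLD",
]

# Raw BLOSUM62 local-alignment score above which a hit is considered
# significant — the thresholded stand-in for a BLAST E-value cutoff.
# Calibrated against a null of unrelated random protein pairs of length
# ~300 (see the methods note); together with the 30% query-coverage
# requirement, random pairs pass the assignment predicate at well under
# 1e-4.
DEFAULT_SCORE_THRESHOLD = 80


@dataclass
class ProteinFamily:
    family_id: str
    representative_protein: str
    member_proteins: list[str] = field(default_factory=list)


def _match(query: str, rep: str, min_id: float, min_cov: float) -> bool:
    aln = seqcore.align_pair(query, rep, mode="local", alphabet="protein")
    if aln is None:
        return False
    shorter = min(len(query), len(rep))
    span = min(aln.query_end - aln.query_start, aln.subject_end - aln.subject_start)
    return aln.identity >= min_id and span / shorter >= min_cov


def cluster_proteins(
    proteins: dict[str, str],
    min_id: float = 0.5,
    min_cov: float = 0.9,
) -> list[ProteinFamily]:
    """Greedy incremental clustering into nonredundant protein families.

    Input order does not matter: proteins are processed by descending
    length, ties by id.  Each joins the first family (in creation order)
    whose representative matches at the identity/coverage thresholds.
    """
    ordered = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    families: list[ProteinFamily] = []
    for pid in ordered:
        seq = proteins[pid]
        joined = False
        for fam in families:
            if _match(seq, proteins[fam.representative_protein], min_id, min_cov):
                fam.member_proteins.append(pid)
                joined = True
                break
        if not joined:
            families.append(ProteinFamily(
                family_id=f"NPF{len(families) + 1:05d}",
                representative_protein=pid,
                member_proteins=[pid],
            ))
    return families


def assign_to_families(
    queries: dict[str, str],
    families: list[ProteinFamily],
    representatives: dict[str, str],
    min_aln_cov: float = 0.30,
    score_threshold: int = DEFAULT_SCORE_THRESHOLD,
) -> dict[str, str | None]:
    """Best-scoring family per query, or None when no hit clears the bar.

    A hit must cover >= ``min_aln_cov`` of the query and score at least
    ``score_threshold``; ties go to the smaller family id.
    """
    out: dict[str, str | None] = {}
    for qid, seq in queries.items():
        best: tuple[int, str] | None = None
        for fam in families:
            rep = representatives[fam.representative_protein]
            aln = seqcore.align_pair(seq, rep, mode="local", alphabet="protein")
            if aln is None:
                continue
            if aln.query_coverage < min_aln_cov or aln.score < score_threshold:
                continue
            cand = (-aln.score, fam.family_id)
            if best is None or cand < best:
                best = cand
        out[qid] = best[1] if best else None
    return out


# ---------------------------------------------------------------------------
# KEGG module definitions


@dataclass(frozen=True)
class KEGGModuleDef:
    """A parsed module: list of top-level step expressions (AST nodes)."""

    module_id: str
    definition: str
    steps: tuple = ()

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id} has no steps")


_TOKEN_RE = re.compile(r"\s+|,|\+|\(|\)|-|[A-Za-z]\w*")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise ValueError(
                f"unparseable module definition at position {pos}: {text[pos]!r}")
        tok = m.group(0)
        tokens.append(" " if tok.isspace() else tok)
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: seq := or (' ' or)* ;  or := and (',' and)* ;
    and := atom ('+' atom)* ;  atom := KO | '(' seq ')' | '-' atom."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> str:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse_seq(self) -> tuple:
        parts = [self.parse_or()]
        while self.peek() == " ":
            self.next()
            if self.peek() in (None, ")"):
                break
            parts.append(self.parse_or())
        parts = [p for p in parts if p is not None]
        return ("AND", tuple(parts)) if len(parts) != 1 else parts[0]

    def parse_or(self) -> tuple | None:
        parts = [self.parse_and()]
        while self.peek() == ",":
            self.next()
            parts.append(self.parse_and())
        kept = [p for p in parts if p is not None]
        if not kept:
            return None
        return ("OR", tuple(kept)) if len(kept) != 1 else kept[0]

    def parse_and(self) -> tuple | None:
        parts = [self.parse_atom()]
        while self.peek() == "+":
            self.next()
            parts.append(self.parse_atom())
        kept = [p for p in parts if p is not None]
        if not kept:
            return None
        return ("AND", tuple(kept)) if len(kept) != 1 else kept[0]

    def parse_atom(self) -> tuple | None:
        tok = self.peek()
        if tok is None:
            raise ValueError(f"unexpected end of definition at token {self.i}")
        if tok == "-":
            self.next()
            self.parse_atom()  # optional component: parsed and discarded
            return None
        if tok == "(":
            self.next()
            inner = self.parse_seq()
            if self.peek() != ")":
                raise ValueError(f"unbalanced parenthesis at token {self.i}")
            self.next()
            return inner
        if tok in (")", ",", "+", " "):
            raise ValueError(f"unexpected {tok!r} at token {self.i}")
        return ("KO", self.next())


def parse_module_definition(module_id: str, definition: str) -> KEGGModuleDef:
    """Parse a module definition string into top-level steps."""
    tokens = _tokenize(definition.strip())
    parser = _Parser(tokens)
    steps = []
    while parser.peek() is not None:
        if parser.peek() == " ":
            parser.next()
            continue
        step = parser.parse_or()
        if step is not None:
            steps.append(step)
    if parser.i != len(tokens):
        raise ValueError(f"trailing tokens at position {parser.i}")
    return KEGGModuleDef(module_id=module_id, definition=definition,
                         steps=tuple(steps))


def _eval(node: tuple, ko_set: set[str]) -> bool:
    kind = node[0]
    if kind == "KO":
        return node[1] in ko_set
    if kind == "AND":
        return all(_eval(c, ko_set) for c in node[1])
    if kind == "OR":
        return any(_eval(c, ko_set) for c in node[1])
    raise ValueError(f"bad AST node {node!r}")


def module_completeness(ko_set: set[str], module: KEGGModuleDef) -> float:
    """Fraction of top-level steps satisfied by ``ko_set``."""
    if not module.steps:
        return 0.0
    satisfied = sum(1 for step in module.steps if _eval(step, ko_set))
    return satisfied / len(module.steps)
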