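"""SNV calling, codon-aware classification, and pN/pS-style selection pressure.

Variants are called from per-site base-count pileups under a binomial
sequencing-error null (per-base error rate, split evenly over the three
non-reference bases) with Benjamini-Hochberg control across all tested
site/alternative pairs.  Reported records must clear three filters at once:
depth >= 5 reads, minor-allele frequency >= 0.05, and FDR q <= 1e-6.

Each SNV is classified by substituting the alternative base into its
containing codon (strand-resolved) and translating both codons with the
bacterial code: same amino acid -> synonymous, different -> nonsynonymous,
outside any gene -> intergenic.

The selection-pressure statistic is a Ka/Ks (pN/pS) ratio.  Raw counts of
nonsynonymous vs synonymous SNVs are biased by codon structure (roughly 3x
more nonsynonymous opportunities), so counts are normalised by
Nei-Gojobori-style expected site counts; under neutral accumulation the
normalised ratio is 1, below 1 indicates purifying (negative) selection and
above 1 positive selection.  Per-sample counts are additionally divided by
the species' mean sequencing depth in that sample so samples of unequal
depth are comparable.  Both the site-normalised ratio (headline) and the
raw-count ratio are reported.
"""

from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_qc import GeneRecord
from .seqcore import translate

__all__ = [
    "SNVRecord",
    "call_snvs",
    "classify_substitution",
    "classify_snvs",
    "count_sites",
    "selection_pressure",
    "cog_selection",
    "GeneIndex",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class SNVRecord:
    """A called variant (position 0-based in memory, 1-based in TSV)."""

    contig: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_freq: float
    p_value: float
    q_value: float
    snv_class: str | None = None
    gene_id: str | None = None
    cog_category: str | None = None


def call_snvs(
    pileup: pd.DataFrame,
    min_depth: int = 5,
    min_freq: float = 0.05,
    fdr: float = 1e-6,
    error_rate: float = 0.001,
) -> list[SNVRecord]:
    """Call SNVs from a pileup table (columns contig_id, pos, ref, A, C, G, T).

    ``pos`` is 1-based as read from disk.  Every non-reference base with a
    positive count is tested against the error null; BH correction runs over
    all tests; a site is reported (with its most frequent passing
    alternative) only if depth, frequency and q-value filters all hold.
    """
    required = {"contig_id", "pos", "ref", "A", "C", "G", "T"}
    missing = required - set(pileup.columns)
    if missing:
        raise ValueError(f"pileup missing columns {sorted(missing)}")
    counts = pileup[list(_BASES)].to_numpy()
    if counts.size and (counts < 0).any():
        bad = int(np.argwhere((counts < 0).any(axis=1))[0][0])
        raise ValueError(f"malformed pileup row {bad + 1}: negative count")
    depth = counts.sum(axis=1)
    refs = pileup["ref"].str.upper().to_numpy()

    tests: list[tuple[int, int]] = []  # (row index, base index)
    pvals: list[float] = []
    for bi, base in enumerate(_BASES):
        mask = (refs != base) & (counts[:, bi] > 0)
        rows = np.nonzero(mask)[0]
        if rows.size == 0:
            continue
        c = counts[rows, bi]
        d = depth[rows]
        p = stats.binom.sf(c - 1, d, error_rate / 3.0)
        tests.extend(zip(rows.tolist(), itertools.repeat(bi)))
        pvals.extend(p.tolist())
    if not tests:
        return []
    qvals = stats.false_discovery_control(np.asarray(pvals), method="bh")

    best: dict[int, tuple[int, int, float, float]] = {}
    for (row, bi), p, q in zip(tests, pvals, qvals):
        d = int(depth[row])
        c = int(counts[row, bi])
        if d < min_depth or c / d < min_freq or q > fdr:
            continue
        prev = best.get(row)
        # keep the most frequent passing alternative; ties to earlier base
        if prev is None or c > prev[1]:
            best[row] = (bi, c, p, q)
    records = []
    for row in sorted(best):
        bi, c, p, q = best[row]
        d = int(depth[row])
        records.append(SNVRecord(
            contig=str(pileup["contig_id"].iat[row]),
            position=int(pileup["pos"].iat[row]) - 1,
            ref=str(refs[row]),
            alt=_BASES[bi],
            depth=d,
            alt_freq=c / d,
            p_value=float(p),
            q_value=float(q),
        ))
    return records


class GeneIndex:
    """Sorted per-contig gene lookup (genes assumed non-overlapping)."""

    def __init__(self, genes: list[GeneRecord]):
        self._by_contig: dict[str, tuple[list[int], list[GeneRecord]]] = {}
        for contig in {g.contig for g in genes}:
            ordered = sorted((g for g in genes if g.contig == contig),
                             key=lambda g: g.start)
            self._by_contig[contig] = ([g.start for g in ordered], ordered)

    def containing(self, contig: str, pos: int) -> GeneRecord | None:
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, ordered = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and ordered[i].start <= pos < ordered[i].end:
            return ordered[i]
        return None


def classify_substitution(
    contig_seq: str,
    gene: GeneRecord | None,
    pos: int,
    alt: str,
) -> str | None:
    """Class of substituting ``alt`` at ``pos`` (0-based) given its gene.

    Returns ``"intergenic"`` when ``gene`` is None, ``"synonymous"`` or
    ``"nonsynonymous"`` otherwise, and None when the containing codon holds
    an ambiguity code (such sites are excluded from analysis).
    """
    if pos >= len(contig_seq):
        raise ValueError(f"position {pos} beyond contig of length {len(contig_seq)}")
    if gene is None:
        return "intergenic"
    offset = pos - gene.start
    codon_i = offset // 3
    c0 = gene.start + 3 * codon_i
    codon = contig_seq[c0 : c0 + 3]
    if any(b not in "ACGT" for b in codon.upper()):
        return None
    within = offset - 3 * codon_i
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    ref_aa = translate(codon, gene.strand)
    alt_aa = translate(alt_codon, gene.strand)
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def classify_snvs(
    snvs: list[SNVRecord],
    genes: list[GeneRecord],
    contigs: dict[str, str],
) -> list[SNVRecord]:
    """Annotate records in place with snv_class, gene_id and COG category.

    Records whose codon is ambiguous are dropped from the returned list.
    """
    index = GeneIndex(genes)
    kept = []
    for rec in snvs:
        gene = index.containing(rec.contig, rec.position)
        cls = classify_substitution(contigs[rec.contig], gene, rec.position, rec.alt)
        if cls is None:
            continue
        rec.snv_class = cls
        rec.gene_id = gene.gene_id if gene else None
        rec.cog_category = gene.cog if gene else None
        kept.append(rec)
    return kept


def _codon_syn_fractions() -> dict[str, tuple[float, float, float]]:
    """Per codon, fraction of the 3 substitutions at each position that are
    synonymous (Nei-Gojobori site counting)."""
    table = {}
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        aa = translate(codon)
        fracs = []
        for i in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[i]:
                    continue
                if translate(codon[:i] + b + codon[i + 1 :]) == aa:
                    syn += 1
            fracs.append(syn / 3.0)
        table[codon] = tuple(fracs)
    return table


_SYN_FRACTIONS = _codon_syn_fractions()


def count_sites(
    genes: list[GeneRecord],
    contigs: dict[str, str],
) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous site counts over all genes.

    Per coding position the fraction of the three possible substitutions
    that preserve the amino acid contributes to the synonymous total, the
    remainder to the nonsynonymous total.  Codons with ambiguity codes are
    skipped.
    """
    syn = nonsyn = 0.0
    for gene in genes:
        cds = contigs[gene.contig][gene.start : gene.end].upper()
        if gene.strand == "-":
            from .seqcore import reverse_complement
            cds = reverse_complement(cds)
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            fracs = _SYN_FRACTIONS.get(codon)
            if fracs is None:
                continue
            s = sum(fracs)
            syn += s
            nonsyn += 3.0 - s
    return syn, nonsyn


def selection_pressure(
    snvs: pd.DataFrame,
    sites: dict[str, tuple[float, float]],
    sample_environment: dict[str, str],
    depths: dict[tuple[str, str], float],
    method: str = "per_sample",
    environments: tuple[str, ...] = ("sebaceous", "moist", "dry"),
) -> pd.DataFrame:
    """Ka/Ks selection statistics per species x skin environment.

    Parameters
    ----------
    snvs : DataFrame with columns species_id, sample_id, snv_class.
    sites : per species, (syn_sites, nonsyn_sites) from :func:`count_sites`.
    sample_environment : sample_id -> environment label.
    depths : (species_id, sample_id) -> mean sequencing depth of the species
        in that sample, used to correct for unequal depth between samples.
    method : "per_sample" averages the per-sample ka'/ks' ratios (samples
        without synonymous SNVs are excluded and counted); "pooled" forms
        the ratio from depth-corrected counts pooled over samples.
    """
    if method not in ("per_sample", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    for s in snvs["sample_id"].unique():
        if s not in sample_environment:
            raise ValueError(f"sample {s!r} has no environment label")
        if sample_environment[s] not in environments:
            raise ValueError(
                f"unknown environment {sample_environment[s]!r} for sample {s!r}")
    rows = []
    for (species, env), grp in _group_by_env(snvs, sample_environment):
        syn_sites, nonsyn_sites = sites[species]
        per_sample = []
        excluded = 0
        pooled_ka = pooled_ks = 0.0
        n_syn = n_nonsyn = n_inter = 0
        depth_sum = 0.0
        samples = sorted(grp["sample_id"].unique())
        for sample in samples:
            sub = grp[grp["sample_id"] == sample]
            s = int((sub["snv_class"] == "synonymous").sum())
            n = int((sub["snv_class"] == "nonsynonymous").sum())
            i = int((sub["snv_class"] == "intergenic").sum())
            n_syn += s
            n_nonsyn += n
            n_inter += i
            d = depths[(species, sample)]
            depth_sum += d
            ka = n / (d * nonsyn_sites) if nonsyn_sites > 0 else 0.0
            ks = s / (d * syn_sites) if syn_sites > 0 else 0.0
            pooled_ka += ka
            pooled_ks += ks
            if ks == 0.0:
                excluded += 1
            else:
                per_sample.append(ka / ks)
        if method == "per_sample":
            ka_ks = float(np.mean(per_sample)) if per_sample else np.nan
        else:
            ka_ks = pooled_ka / pooled_ks if pooled_ks > 0 else np.nan
        rows.append({
            "species_id": species,
            "environment": env,
            "n_samples": len(samples),
            "n_excluded": excluded,
            "n_syn": n_syn,
            "n_nonsyn": n_nonsyn,
            "n_intergenic": n_inter,
            "mean_depth": depth_sum / len(samples) if samples else np.nan,
            "syn_sites": syn_sites,
            "nonsyn_sites": nonsyn_sites,
            "ka_ks": ka_ks,
            "ka_ks_raw": n_nonsyn / n_syn if n_syn else np.nan,
            "selection": ("negative" if ka_ks < 1 else "positive")
            if np.isfinite(ka_ks) else "undefined",
        })
    return pd.DataFrame(rows).sort_values(
        ["species_id", "environment"]).reset_index(drop=True)


def _group_by_env(snvs: pd.DataFrame, sample_environment: dict[str, str]):
    df = snvs.copy()
    df["environment"] = df["sample_id"].map(sample_environment)
    for key, grp in df.groupby(["species_id", "environment"], sort=True):
        yield key, grp


def cog_selection(
    snvs: pd.DataFrame,
    genes: list[GeneRecord],
    contigs: dict[str, str],
    depths: dict[str, float],
    min_snvs: int = 10,
) -> pd.DataFrame:
    """Per-COG-category site-normalised Ka/Ks on pooled depth-corrected counts.

    ``snvs`` needs columns sample_id, snv_class, cog_category; ``depths``
    maps sample_id to mean depth.  Categories with fewer than ``min_snvs``
    classified SNVs, or with no synonymous signal, come back undefined
    (NaN) rather than infinite.
    """
    cog_sites: dict[str, tuple[float, float]] = {}
    for letter in sorted({g.cog for g in genes if g.cog}):
        sub = [g for g in genes if g.cog == letter]
        cog_sites[letter] = count_sites(sub, contigs)
    rows = []
    coding = snvs[snvs["snv_class"].isin(["synonymous", "nonsynonymous"])]
    for letter, grp in coding.groupby("cog_category", sort=True):
        if letter not in cog_sites:
            continue
        syn_sites, nonsyn_sites = cog_sites[letter]
        pooled_ka = pooled_ks = 0.0
        for sample, sub in grp.groupby("sample_id"):
            d = depths[sample]
            pooled_ka += (sub["snv_class"] == "nonsynonymous").sum() / (d * nonsyn_sites)
            pooled_ks += (sub["snv_class"] == "synonymous").sum() / (d * syn_sites)
        n = len(grp)
        defined = n >= min_snvs and pooled_ks > 0
        rows.append({
            "cog_category": letter,
            "n_snvs": n,
            "ka_ks": pooled_ka / pooled_ks if defined else np.nan,
        })
    return pd.DataFrame(rows, columns=["cog_category", "n_snvs", "ka_ks"])
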