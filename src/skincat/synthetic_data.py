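"""Synthetic metagenome generation with exact ground truth.

Every downstream stage is exercised on data built here: unrelated species
genomes carrying non-overlapping protein-coding genes on both strands,
derived genomes at controlled nucleotide identity, bins with exact
marker-based completeness/contamination, per-sample coverage from known
abundances, read pileups with controlled synonymous/nonsynonymous/
intergenic composition, planted cross-taxon gene transfers, and
biosynthetic gene clusters with planted shared genes.

Design choices that shape the data:

* Genes are 300-1500 nt, ATG-initiated and stop-terminated, placed with
  50-500 nt intergenic spacers on uniformly random strands — bacterial-like
  coding density of roughly 80-90%.
* Marker loci are 100 designated short (300 nt) genes tagged in the GFF3
  ``marker_id`` attribute, one per dedicated contig, so bin completeness
  and contamination can be realised exactly by dropping or adding whole
  marker contigs.
* Coverage noise is lognormal (mean 1, given CV), the standard
  overdispersion model for per-contig depth.

All generators are deterministic per seed: the same seed yields
byte-identical FASTA/GFF3/TSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_qc import GeneRecord, GenomeBin, MarkerSet
from .seqcore import reverse_complement
from .snv_selection import GeneIndex, classify_substitution

__all__ = [
    "SimulationTruth",
    "SpeciesSet",
    "generate_species_set",
    "mutate_to_ani",
    "make_bin",
    "simulate_coverage",
    "simulate_pileup",
    "simulate_selection_pileup",
    "plant_hgt",
    "simulate_bgcs",
    "simulate_hgt_scenario",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_COG_LETTERS = "CEGIJKLMOPT"


@dataclass
class SimulationTruth:
    """Ground truth of one simulated scenario."""

    seed: int
    species_assignments: dict[str, str] = field(default_factory=dict)
    true_abundances: pd.DataFrame | None = None
    planted_snvs: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    planted_hgts: list[tuple[str, str, str, float]] = field(default_factory=list)
    shared_bgc_genes: list[tuple[str, str, tuple[str, str]]] = field(default_factory=list)

    def validate(self, genomes: dict[str, GenomeBin]) -> None:
        """Check internal consistency (abundance sums, SNV reference bases)."""
        if self.true_abundances is not None:
            sums = self.true_abundances.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("per-sample true abundances must sum to 1")
        by_contig = {}
        for b in genomes.values():
            by_contig.update(b.contigs)
        for contig, pos, ref, _alt, _cls in self.planted_snvs:
            if contig in by_contig and by_contig[contig][pos] != ref:
                raise ValueError(f"planted SNV ref mismatch at {contig}:{pos}")


@dataclass
class SpeciesSet:
    genomes: dict[str, GenomeBin]
    marker_set: MarkerSet
    truth: SimulationTruth


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG-initiated, stop-terminated CDS with no internal stop codons."""
    assert length % 3 == 0 and length >= 9
    n_internal = length // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_internal + 1:
        codon = "".join(rng.choice(_BASES, 3))
        if codon not in _STOPS:
            codons.append(codon)
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def generate_species_set(
    n_species: int,
    genome_length: int = 50_000,
    n_genes_per_genome: int = 30,
    taxon_tree_depth: int = 3,
    seed: int = 0,
    n_markers: int = 100,
    n_top_groups: int = 2,
    n_regular_contigs: int = 4,
) -> SpeciesSet:
    """Generate ``n_species`` unrelated genomes with gene models and taxa.

    Each genome consists of ``n_regular_contigs`` contigs of
    ``genome_length`` total holding the protein-coding genes, plus
    ``n_markers`` dedicated short marker contigs.  Taxon labels form a
    ``taxon_tree_depth``-level hierarchy (phylum-like top level shared
    between species of the same group, leaf unique per species).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if taxon_tree_depth < 1:
        raise ValueError("taxon_tree_depth must be >= 1")
    rng = np.random.default_rng(seed)
    gene_lengths = [int(rng.integers(100, 501)) * 3 for _ in range(n_genes_per_genome)]
    min_required = sum(gene_lengths) + 50 * (n_genes_per_genome + n_regular_contigs)
    if genome_length < min_required:
        raise ValueError(
            f"genome_length {genome_length} cannot pack {n_genes_per_genome} "
            f"genes; at least {min_required} nt required")

    genomes: dict[str, GenomeBin] = {}
    truth = SimulationTruth(seed=seed)
    for si in range(n_species):
        sp = f"sp{si + 1}"
        group = si % max(1, n_top_groups)
        levels = [f"P{group + 1}"]
        for d in range(1, taxon_tree_depth):
            levels.append(f"P{group + 1}.L{d}.{si + 1}")
        taxon = ";".join(levels)
        contigs: dict[str, str] = {}
        genes: list[GeneRecord] = []
        # regular contigs with protein-coding genes
        per_contig = genome_length // n_regular_contigs
        gi = 0
        assignment = [
            [g for g in range(n_genes_per_genome) if g % n_regular_contigs == c]
            for c in range(n_regular_contigs)
        ]
        for c in range(n_regular_contigs):
            name = f"{sp}_c{c + 1}"
            parts: list[str] = []
            pos = 0
            remaining = [gene_lengths[g] for g in assignment[c]]
            if per_contig < sum(remaining) + 50 * len(remaining):
                need = (sum(remaining) + 50 * len(remaining)) * n_regular_contigs
                raise ValueError(
                    f"genome_length {genome_length} cannot pack "
                    f"{n_genes_per_genome} genes; at least {need} nt required")
            for gi_c, g in enumerate(assignment[c]):
                # cap the spacer so the remaining genes always fit
                slack = per_contig - pos - sum(remaining[gi_c:]) \
                    - 50 * (len(remaining) - gi_c)
                spacer = 50 + int(rng.integers(0, min(451, max(1, slack + 1))))
                parts.append(_random_dna(rng, spacer))
                pos += spacer
                cds = _random_cds(rng, gene_lengths[g])
                strand = "+" if rng.random() < 0.5 else "-"
                placed = cds if strand == "+" else reverse_complement(cds)
                genes.append(GeneRecord(
                    gene_id=f"{sp}_g{g + 1}",
                    contig=name,
                    start=pos,
                    end=pos + len(cds),
                    strand=strand,
                    ko=f"K{g + 1:05d}",
                    cog=_COG_LETTERS[int(rng.integers(len(_COG_LETTERS)))],
                ))
                parts.append(placed)
                pos += len(cds)
                gi += 1
            if pos > per_contig:
                raise ValueError(
                    f"gene packing overflow on contig {name}: need {pos} nt, "
                    f"have {per_contig}; increase genome_length to "
                    f">= {pos * n_regular_contigs}")
            parts.append(_random_dna(rng, per_contig - pos))
            contigs[name] = "".join(parts)
        # marker contigs, one marker gene each
        for mi in range(n_markers):
            name = f"{sp}_mk{mi + 1}"
            left = int(rng.integers(50, 201))
            right = int(rng.integers(50, 201))
            cds = _random_cds(rng, 300)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = cds if strand == "+" else reverse_complement(cds)
            contigs[name] = _random_dna(rng, left) + placed + _random_dna(rng, right)
            genes.append(GeneRecord(
                gene_id=f"{sp}_mkg{mi + 1}",
                contig=name,
                start=left,
                end=left + 300,
                strand=strand,
                marker_id=f"MK{mi + 1:04d}",
            ))
        genomes[sp] = GenomeBin(bin_id=sp, contigs=contigs, genes=genes, taxon=taxon)
        truth.species_assignments[sp] = sp
    marker_set = MarkerSet(tuple(f"MK{i + 1:04d}" for i in range(n_markers)))
    return SpeciesSet(genomes=genomes, marker_set=marker_set, truth=truth)


def _rename(bin_: GenomeBin, new_id: str, contigs: dict[str, str],
            genes: list[GeneRecord]) -> GenomeBin:
    """Re-prefix contig names with the new bin id and remap genes."""
    mapping = {c: c.replace(bin_.bin_id, new_id, 1) if c.startswith(bin_.bin_id)
               else f"{new_id}_{c}" for c in contigs}
    new_contigs = {mapping[c]: s for c, s in contigs.items()}
    new_genes = [
        GeneRecord(g.gene_id, mapping[g.contig], g.start, g.end, g.strand,
                   g.marker_id, g.ko, g.cog)
        for g in genes
    ]
    return GenomeBin(bin_id=new_id, contigs=new_contigs, genes=new_genes,
                     taxon=bin_.taxon, source_sample=bin_.source_sample)


def mutate_to_ani(genome: GenomeBin, target_ani: float, seed: int,
                  new_bin_id: str | None = None) -> GenomeBin:
    """Derive a genome at a controlled nucleotide identity.

    Substitutes ``round((1 - target_ani) * length)`` uniformly chosen
    distinct positions to a different base; gene coordinates are preserved.
    """
    if not (0.8 <= target_ani <= 1.0):
        raise ValueError("target_ani must be in [0.8, 1.0]")
    rng = np.random.default_rng(seed)
    names = sorted(genome.contigs)
    lengths = np.array([len(genome.contigs[c]) for c in names])
    total = int(lengths.sum())
    n_sub = round((1.0 - target_ani) * total)
    flat = rng.choice(total, size=n_sub, replace=False)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    arrays = {c: np.frombuffer(genome.contigs[c].encode(), dtype="S1").copy()
              for c in names}
    for p in np.sort(flat):
        ci = int(np.searchsorted(offsets, p, side="right")) - 1
        off = int(p - offsets[ci])
        arr = arrays[names[ci]]
        cur = arr[off].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[off] = rng.choice(choices).encode()
    new_contigs = {c: arrays[c].tobytes().decode() for c in names}
    new_id = new_bin_id or f"{genome.bin_id}_mut"
    return _rename(genome, new_id, new_contigs, genome.genes)


def make_bin(
    genome: GenomeBin,
    completeness: float,
    contamination: float,
    foreign_pool: list[GenomeBin],
    marker_set: MarkerSet,
    seed: int,
    bin_id: str | None = None,
) -> GenomeBin:
    """Degrade a genome into a bin with exact marker-based quality.

    Drops whole marker contigs until exactly ``round(completeness * M)``
    markers remain, then adds foreign marker contigs (carrying marker ids
    already present) until exactly ``round(contamination * M)`` surplus
    copies exist.
    """
    if not (0 < completeness <= 1):
        raise ValueError("completeness must be in (0, 1]")
    if not (0 <= contamination <= 0.2):
        raise ValueError("contamination must be in [0, 0.2]")
    if contamination > 0 and not foreign_pool:
        raise ValueError("foreign pool empty while contamination > 0")
    rng = np.random.default_rng(seed)
    m = len(marker_set)
    keep_n = round(completeness * m)
    dup_n = round(contamination * m)
    marker_genes = {g.marker_id: g for g in genome.genes if g.marker_id}
    have = sorted(set(marker_genes) & set(marker_set.marker_ids))
    if keep_n > len(have):
        raise ValueError(f"genome has only {len(have)} of {m} markers")
    keep = sorted(rng.choice(have, size=keep_n, replace=False))
    drop_contigs = {marker_genes[mid].contig for mid in set(have) - set(keep)}
    contigs = {c: s for c, s in genome.contigs.items() if c not in drop_contigs}
    genes = [g for g in genome.genes if g.contig not in drop_contigs]
    if dup_n > len(keep):
        raise ValueError("requested contamination exceeds retained markers")
    dup_ids = sorted(rng.choice(keep, size=dup_n, replace=False)) if dup_n else []
    for i, mid in enumerate(dup_ids):
        donor = foreign_pool[int(rng.integers(len(foreign_pool)))]
        src = next(g for g in donor.genes if g.marker_id == mid)
        new_contig = f"{genome.bin_id}_foreign{i + 1}"
        contigs[new_contig] = donor.contigs[src.contig]
        genes.append(GeneRecord(
            gene_id=f"{src.gene_id}_dup{i + 1}", contig=new_contig,
            start=src.start, end=src.end, strand=src.strand,
            marker_id=src.marker_id, ko=src.ko, cog=src.cog))
    new_id = bin_id or f"{genome.bin_id}_bin"
    return _rename(GenomeBin(genome.bin_id, contigs, genes, taxon=genome.taxon),
                   new_id, contigs, genes)


def simulate_coverage(
    true_abundances: pd.DataFrame,
    genomes: dict[str, GenomeBin],
    depth_scale: float = 20.0,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-contig per-sample depths from known species abundances.

    ``true_abundances`` is species x sample (columns are samples, each
    summing to 1).  Depth = depth_scale x abundance x lognormal noise with
    mean 1 and coefficient of variation ``noise_cv`` (0 disables noise), so
    all contigs of a species share one expected depth.
    """
    sums = true_abundances.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("each sample's abundances must sum to 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    rows = []
    for sample in true_abundances.columns:
        for species in true_abundances.index:
            ab = float(true_abundances.loc[species, sample])
            for contig in sorted(genomes[species].contigs):
                noise = (float(rng.lognormal(-sigma**2 / 2.0, sigma))
                         if sigma > 0 else 1.0)
                rows.append({
                    "contig_id": contig,
                    "sample_id": sample,
                    "depth": depth_scale * ab * noise,
                })
    return pd.DataFrame(rows)


def _plant_sites(
    bin_: GenomeBin,
    classes_needed: dict[str, int],
    rng: np.random.Generator,
) -> list[tuple[str, int, str, str, str]]:
    """Pick distinct positions+alts realising the requested class counts.

    Synonymous/nonsynonymous picks are rejection-sampled from coding
    positions and verified against the codon oracle before emission.
    """
    index = GeneIndex(bin_.genes)
    names = sorted(bin_.contigs)
    coding: list[tuple[str, int]] = []
    for g in sorted(bin_.genes, key=lambda g: (g.contig, g.start)):
        coding.extend((g.contig, p) for p in range(g.start, g.end))
    coding_set = set(coding)
    intergenic: list[tuple[str, int]] = []
    for c in names:
        intergenic.extend(
            (c, p) for p in range(len(bin_.contigs[c])) if (c, p) not in coding_set)
    used: set[tuple[str, int]] = set()
    planted: list[tuple[str, int, str, str, str]] = []
    needed = dict(classes_needed)

    def try_plant(pool: list[tuple[str, int]], want_classes: set[str]) -> None:
        budget = 200 * sum(needed[c] for c in want_classes) + 1000
        while any(needed[c] > 0 for c in want_classes) and budget > 0:
            budget -= 1
            contig, pos = pool[int(rng.integers(len(pool)))]
            if (contig, pos) in used:
                continue
            ref = bin_.contigs[contig][pos]
            alt = "ACGT"[int(rng.integers(4))]
            if alt == ref:
                continue
            gene = index.containing(contig, pos)
            cls = classify_substitution(bin_.contigs[contig], gene, pos, alt)
            if cls is None or cls not in want_classes or needed.get(cls, 0) <= 0:
                continue
            used.add((contig, pos))
            planted.append((contig, pos, ref, alt, cls))
            needed[cls] -= 1
        if any(needed[c] > 0 for c in want_classes):
            raise RuntimeError("could not place requested SNV composition")

    if needed.get("intergenic", 0) > 0:
        try_plant(intergenic, {"intergenic"})
    if needed.get("synonymous", 0) > 0 or needed.get("nonsynonymous", 0) > 0:
        try_plant(coding, {"synonymous", "nonsynonymous"})
    return planted


def _emit_pileup(
    bin_: GenomeBin,
    planted: list[tuple[str, int, str, str, str]],
    depth: int,
    alt_freq_range: tuple[float, float],
    error_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Base-count table over every genome position, errors plus planted alts."""
    planted_by_site = {(c, p): (ref, alt) for c, p, ref, alt, _ in planted}
    frames = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for contig in sorted(bin_.contigs):
        seq = bin_.contigs[contig]
        L = len(seq)
        counts = np.zeros((L, 4), dtype=np.int64)
        ref_idx = np.array([base_idx.get(b, 0) for b in seq])
        counts[np.arange(L), ref_idx] = depth
        if error_rate > 0:
            n_err = rng.binomial(depth, error_rate, size=L)
            for pos in np.nonzero(n_err)[0]:
                alts = [i for i in range(4) if i != ref_idx[pos]]
                split = rng.multinomial(n_err[pos], [1 / 3] * 3)
                for ai, cnt in zip(alts, split):
                    counts[pos, ai] += cnt
                counts[pos, ref_idx[pos]] -= n_err[pos]
        for (c, p), (_ref, alt) in planted_by_site.items():
            if c != contig:
                continue
            f = rng.uniform(*alt_freq_range)
            alt_n = rng.binomial(depth, f)
            counts[p, base_idx[alt]] += alt_n
            counts[p, ref_idx[p]] = max(0, counts[p, ref_idx[p]] - alt_n)
        frames.append(pd.DataFrame({
            "contig_id": contig,
            "pos": np.arange(1, L + 1),
            "ref": list(seq),
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_pileup(
    bin_: GenomeBin,
    n_snvs: int,
    nonsyn_fraction_target: float,
    intergenic_fraction_target: float,
    depth: int = 50,
    alt_freq_range: tuple[float, float] = (0.1, 0.9),
    error_rate: float = 0.001,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, int, str, str, str]]]:
    """Pileup with a controlled syn/nonsyn/intergenic SNV composition.

    Plants ``n_snvs`` variants at distinct positions with class counts
    rounded from the targets (remainder synonymous); every other site
    receives only sequencing-error reads at ``error_rate``.
    """
    if nonsyn_fraction_target + intergenic_fraction_target > 1.0 + 1e-12:
        raise ValueError("class fraction targets must sum to <= 1")
    rng = np.random.default_rng(seed)
    n_non = round(n_snvs * nonsyn_fraction_target)
    n_int = round(n_snvs * intergenic_fraction_target)
    n_syn = n_snvs - n_non - n_int
    planted = _plant_sites(bin_, {
        "synonymous": n_syn, "nonsynonymous": n_non, "intergenic": n_int,
    }, rng)
    pileup = _emit_pileup(bin_, planted, depth, alt_freq_range, error_rate, rng)
    return pileup, planted


def simulate_selection_pileup(
    bin_: GenomeBin,
    n_snvs: int,
    nonsyn_acceptance: float = 1.0,
    depth: int = 50,
    alt_freq_range: tuple[float, float] = (0.1, 0.9),
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, int, str, str, str]]]:
    """Pileup under an explicit selection model on coding sites.

    Substitutions are proposed uniformly over coding positions and random
    alternative bases; synonymous proposals are always accepted,
    nonsynonymous ones with probability ``nonsyn_acceptance``.  Acceptance
    1 is neutral accumulation (site-normalised Ka/Ks -> 1); lower values
    emulate purifying selection with Ka/Ks -> acceptance.
    """
    if not (0 < nonsyn_acceptance <= 1):
        raise ValueError("nonsyn_acceptance must be in (0, 1]")
    rng = np.random.default_rng(seed)
    index = GeneIndex(bin_.genes)
    coding: list[tuple[str, int]] = []
    for g in sorted(bin_.genes, key=lambda g: (g.contig, g.start)):
        coding.extend((g.contig, p) for p in range(g.start, g.end))
    used: set[tuple[str, int]] = set()
    planted: list[tuple[str, int, str, str, str]] = []
    budget = 1000 * n_snvs + 10_000
    while len(planted) < n_snvs and budget > 0:
        budget -= 1
        contig, pos = coding[int(rng.integers(len(coding)))]
        if (contig, pos) in used:
            continue
        ref = bin_.contigs[contig][pos]
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        gene = index.containing(contig, pos)
        cls = classify_substitution(bin_.contigs[contig], gene, pos, alt)
        if cls is None:
            continue
        if cls == "nonsynonymous" and rng.random() > nonsyn_acceptance:
            continue
        used.add((contig, pos))
        planted.append((contig, pos, ref, alt, cls))
    if len(planted) < n_snvs:
        raise RuntimeError("could not place requested number of SNVs")
    pileup = _emit_pileup(bin_, planted, depth, alt_freq_range, error_rate, rng)
    return pileup, planted


def plant_hgt(
    donor: GenomeBin,
    recipient: GenomeBin,
    gene_id: str,
    divergence: float,
    seed: int,
) -> tuple[GenomeBin, tuple[str, str, str, float]]:
    """Copy a donor gene into the recipient with controlled divergence.

    The donor gene's genomic span is substituted at ``divergence`` fraction
    of positions and appended (behind a 100 nt spacer) to the recipient's
    largest contig; the recipient's gene models gain the transferred copy.
    Returns the modified recipient and the truth tuple
    (donor_bin, recipient_bin, transferred_gene_id, divergence).
    """
    rng = np.random.default_rng(seed)
    src = next((g for g in donor.genes if g.gene_id == gene_id), None)
    if src is None:
        raise ValueError(f"donor has no gene {gene_id!r}")
    seg = list(donor.contigs[src.contig][src.start : src.end])
    n_sub = round(divergence * len(seg))
    for p in rng.choice(len(seg), size=n_sub, replace=False):
        choices = [b for b in "ACGT" if b != seg[p]]
        seg[p] = str(rng.choice(choices))
    seg_s = "".join(seg)
    target = max(recipient.contigs, key=lambda c: len(recipient.contigs[c]))
    spacer = _random_dna(rng, 100)
    old = recipient.contigs[target]
    new_contigs = dict(recipient.contigs)
    new_contigs[target] = old + spacer + seg_s
    new_gene_id = f"{gene_id}__hgt_{recipient.bin_id}"
    new_genes = list(recipient.genes) + [GeneRecord(
        gene_id=new_gene_id, contig=target,
        start=len(old) + 100, end=len(old) + 100 + len(seg_s),
        strand=src.strand, ko=src.ko, cog=src.cog)]
    new_bin = GenomeBin(recipient.bin_id, new_contigs, new_genes,
                        completeness=recipient.completeness,
                        contamination=recipient.contamination,
                        tier=recipient.tier, taxon=recipient.taxon,
                        source_sample=recipient.source_sample)
    return new_bin, (donor.bin_id, recipient.bin_id, new_gene_id, divergence)


_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _mutate_protein(seq: str, identity: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    n_sub = round((1 - identity) * len(arr))
    for p in rng.choice(len(arr), size=n_sub, replace=False):
        choices = [a for a in _AA20 if a != arr[p]]
        arr[p] = str(rng.choice(choices))
    return "".join(arr)


def simulate_bgcs(
    n_families: int = 2,
    bgcs_per_family: int = 4,
    genes_per_bgc: int = 5,
    n_singletons: int = 2,
    shared_identity: float = 0.9,
    gene_length_range: tuple[int, int] = (120, 300),
    genome_taxa: dict[str, str] | None = None,
    seed: int = 0,
):
    """Biosynthetic gene clusters with planted shared-gene structure.

    Each family has a hallmark protein; every member cluster carries a copy
    mutated to ``shared_identity`` plus unique random proteins, so clusters
    of one family connect through the hallmark and families stay disjoint.
    Returns (list of BGCRecord, truth pairs of (bgc_a, bgc_b, (gene_a, gene_b))).
    """
    from .bgc_network import BGCRecord

    rng = np.random.default_rng(seed)
    classes = ["NRPS", "PKS", "terpene", "betalactone", "siderophore"]
    genome_ids = sorted(genome_taxa) if genome_taxa else [
        f"g{i + 1}" for i in range(max(2, n_families))]
    records: list[BGCRecord] = []
    truth: list[tuple[str, str, tuple[str, str]]] = []
    bgc_n = 0
    for fi in range(n_families):
        hallmark = "".join(rng.choice(_AA20, int(rng.integers(*gene_length_range))))
        members = []
        for bi in range(bgcs_per_family):
            bgc_n += 1
            bgc_id = f"bgc{bgc_n}"
            genes = {f"{bgc_id}_hall": _mutate_protein(hallmark, shared_identity, rng)}
            for gi in range(genes_per_bgc - 1):
                genes[f"{bgc_id}_p{gi + 1}"] = "".join(
                    rng.choice(_AA20, int(rng.integers(*gene_length_range))))
            records.append(BGCRecord(
                bgc_id=bgc_id,
                genome_id=genome_ids[bgc_n % len(genome_ids)],
                product_class=classes[fi % len(classes)],
                genes=genes))
            members.append(bgc_id)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                truth.append((members[i], members[j],
                              (f"{members[i]}_hall", f"{members[j]}_hall")))
    for si in range(n_singletons):
        bgc_n += 1
        bgc_id = f"bgc{bgc_n}"
        genes = {
            f"{bgc_id}_p{gi + 1}": "".join(
                rng.choice(_AA20, int(rng.integers(*gene_length_range))))
            for gi in range(genes_per_bgc)
        }
        records.append(BGCRecord(
            bgc_id=bgc_id, genome_id=genome_ids[bgc_n % len(genome_ids)],
            product_class=classes[(n_families + si) % len(classes)], genes=genes))
    return records, truth


def simulate_hgt_scenario(
    n_species_per_group: int = 2,
    n_groups: int = 2,
    n_transfers: int = 3,
    divergence: float | tuple[float, ...] = 0.005,
    genome_length: int = 30_000,
    n_genes_per_genome: int = 20,
    n_markers: int = 10,
    sibling_ani: float = 0.98,
    n_siblings: int = 1,
    seed: int = 0,
) -> tuple[list[GenomeBin], SimulationTruth]:
    """Two-plus taxon groups with sibling genomes and planted transfers.

    Each species contributes its reference genome and ``n_siblings``
    siblings derived at ``sibling_ani`` (so donor groups carry vertical
    homolog support for orientation and phylogenetic screening).
    ``n_transfers`` distinct genes are copied from group-1 donors into
    group-2 recipients at the requested divergence.
    """
    sset = generate_species_set(
        n_species=n_species_per_group * n_groups,
        genome_length=genome_length,
        n_genes_per_genome=n_genes_per_genome,
        taxon_tree_depth=3,
        seed=seed,
        n_markers=n_markers,
        n_top_groups=n_groups,
    )
    rng = np.random.default_rng(seed + 1)
    bins: dict[str, GenomeBin] = {}
    suffixes = "bcdefgh"
    for sp, g in sset.genomes.items():
        bins[sp] = g
        for si in range(n_siblings):
            sib_id = f"{sp}{suffixes[si]}"
            bins[sib_id] = mutate_to_ani(g, sibling_ani,
                                         seed=int(rng.integers(2**31)),
                                         new_bin_id=sib_id)
    groups: dict[str, list[str]] = {}
    for sp, g in sset.genomes.items():
        groups.setdefault(g.taxon.split(";")[0], []).append(sp)
    group_names = sorted(groups)
    donors = groups[group_names[0]]
    recipients = groups[group_names[1]]
    truth = sset.truth
    donor_gene_pool = [
        (sp, g.gene_id) for sp in donors
        for g in sset.genomes[sp].genes if g.marker_id is None
    ]
    divergences = ([divergence] * n_transfers if isinstance(divergence, float)
                   else list(divergence))
    if len(divergences) != n_transfers:
        raise ValueError("need one divergence per transfer")
    chosen = rng.choice(len(donor_gene_pool), size=n_transfers, replace=False)
    for i, idx in enumerate(sorted(chosen)):
        donor_sp, gene_id = donor_gene_pool[int(idx)]
        recipient_sp = recipients[i % len(recipients)]
        new_bin, entry = plant_hgt(
            bins[donor_sp], bins[recipient_sp], gene_id, divergences[i],
            seed=int(rng.integers(2**31)))
        bins[recipient_sp] = new_bin
        truth.planted_hgts.append(entry)
    return list(bins.values()), truth
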