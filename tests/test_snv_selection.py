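"""Variant filters, exhaustive codon-classification oracle, Ka/Ks recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from skincat import snv_selection as sv
from skincat import synthetic_data as sd
from skincat.genome_qc import GeneRecord
from skincat.seqcore import reverse_complement


def _pileup(rows):
    return pd.DataFrame(rows, columns=["contig_id", "pos", "ref",
                                       "A", "C", "G", "T"])


class TestCallSnvs:
    def test_depth_floor(self):
        # strong signal but depth 4: never reported
        recs = sv.call_snvs(_pileup([("c", 1, "A", 1, 3, 0, 0)]))
        assert recs == []

    def test_frequency_floor(self):
        recs = sv.call_snvs(_pileup([("c", 1, "A", 96, 4, 0, 0)]))
        assert recs == []

    def test_clear_signal_reported(self):
        recs = sv.call_snvs(_pileup([("c", 5, "A", 70, 30, 0, 0)]))
        assert len(recs) == 1
        r = recs[0]
        assert (r.position, r.ref, r.alt, r.depth) == (4, "A", "C", 100)
        assert r.alt_freq == pytest.approx(0.3)
        assert r.q_value <= 1e-6

    def test_fdr_filter(self):
        # one non-reference read at depth 5 passes depth and frequency
        # floors but is consistent with sequencing error
        recs = sv.call_snvs(_pileup([("c", 1, "A", 4, 1, 0, 0)]))
        assert recs == []

    def test_most_frequent_alt_kept(self):
        recs = sv.call_snvs(_pileup([("c", 1, "A", 40, 25, 35, 0)]))
        assert len(recs) == 1
        assert recs[0].alt == "G"

    def test_all_filters_hold_on_simulated_pileup(self, genome):
        pile, _ = sd.simulate_pileup(genome, 150, 0.35, 0.1, depth=40,
                                     error_rate=0.002, seed=5)
        for r in sv.call_snvs(pile):
            assert r.depth >= 5
            assert r.alt_freq >= 0.05
            assert r.q_value <= 1e-6


def _oracle_class(codon, within, alt, strand):
    """Independent translate-both-codons oracle via Biopython, table 11."""
    alt_codon = codon[:within] + alt + codon[within + 1:]
    if strand == "-":
        codon, alt_codon = reverse_complement(codon), reverse_complement(alt_codon)
    same = str(Seq(codon).translate(table=11)) == \
        str(Seq(alt_codon).translate(table=11))
    return "synonymous" if same else "nonsynonymous"


class TestClassifySubstitution:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exhaustive_codon_oracle(self, strand):
        """All 64 codons x 3 positions x 3 alts, both strands (3456 cases)."""
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            placed = codon if strand == "+" else reverse_complement(codon)
            gene = GeneRecord("g", "c", 0, 3, strand)
            for pos in range(3):
                for alt in "ACGT":
                    if alt == placed[pos]:
                        continue
                    got = sv.classify_substitution(placed, gene, pos, alt)
                    # map the genomic-forward substitution to coding-strand
                    # codon coordinates for the oracle
                    if strand == "+":
                        expected = _oracle_class(placed, pos, alt, "+")
                    else:
                        expected = _oracle_class(placed, pos, alt, "-")
                    assert got == expected, (codon, strand, pos, alt)

    def test_intergenic(self):
        assert sv.classify_substitution("ACGTACGT", None, 3, "A") == "intergenic"

    def test_ambiguous_codon_excluded(self):
        gene = GeneRecord("g", "c", 0, 3, "+")
        assert sv.classify_substitution("ANG", gene, 0, "C") is None

    def test_position_beyond_contig_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            sv.classify_substitution("ACG", None, 7, "A")

    @pytest.mark.parametrize("codon,pos,alt,expected", [
        ("GCT", 2, "C", "synonymous"),      # GCT->GCC, Ala->Ala
        ("GCT", 0, "C", "nonsynonymous"),   # GCT->CCT, Ala->Pro
    ])
    def test_known_codon_changes(self, codon, pos, alt, expected):
        gene = GeneRecord("g", "c", 0, 3, "+")
        assert sv.classify_substitution(codon, gene, pos, alt) == expected


class TestCountSites:
    def test_fourfold_degenerate_codon(self):
        contigs = {"c": "GGG" * 5}
        genes = [GeneRecord("g", "c", 0, 15, "+")]
        syn, nonsyn = sv.count_sites(genes, contigs)
        assert syn == pytest.approx(5 * 1.0)
        assert nonsyn == pytest.approx(5 * 2.0)

    def test_tryptophan_no_degeneracy(self):
        contigs = {"c": "TGG"}
        syn, nonsyn = sv.count_sites([GeneRecord("g", "c", 0, 3, "+")], contigs)
        assert syn == 0.0
        assert nonsyn == 3.0

    def test_empty_gene_set(self):
        assert sv.count_sites([], {"c": "ACGT"}) == (0.0, 0.0)

    def test_strand_invariance(self, genome):
        """Site counts via recorded strands equal Biopython-translated
        enumeration over coding-strand codons."""
        syn, nonsyn = sv.count_sites(genome.genes, genome.contigs)
        exp_syn = exp_nonsyn = 0.0
        for g in genome.genes:
            cds = genome.gene_sequence(g)
            for i in range(0, len(cds), 3):
                codon = cds[i:i + 3]
                aa = str(Seq(codon).translate(table=11))
                for j in range(3):
                    for b in "ACGT":
                        if b == codon[j]:
                            continue
                        other = codon[:j] + b + codon[j + 1:]
                        if str(Seq(other).translate(table=11)) == aa:
                            exp_syn += 1 / 3
                        else:
                            exp_nonsyn += 1 / 3
        assert syn == pytest.approx(exp_syn)
        assert nonsyn == pytest.approx(exp_nonsyn)


def _selection_run(genome, acceptance, n_snvs, seed):
    pile, _ = sd.simulate_selection_pileup(genome, n_snvs,
                                           nonsyn_acceptance=acceptance,
                                           depth=50, seed=seed)
    recs = sv.classify_snvs(sv.call_snvs(pile), genome.genes, genome.contigs)
    df = pd.DataFrame({"species_id": "sp", "sample_id": "s1",
                       "snv_class": [r.snv_class for r in recs]})
    sites = {"sp": sv.count_sites(genome.genes, genome.contigs)}
    out = sv.selection_pressure(df, sites, {"s1": "dry"}, {("sp", "s1"): 50.0})
    return float(out["ka_ks"].iloc[0])


class TestSelectionPressure:
    def test_zero_nonsyn_gives_zero(self):
        df = pd.DataFrame({"species_id": "sp", "sample_id": "s1",
                           "snv_class": ["synonymous"] * 10})
        out = sv.selection_pressure(df, {"sp": (100.0, 300.0)},
                                    {"s1": "dry"}, {("sp", "s1"): 10.0})
        assert out["ka_ks"].iloc[0] == 0.0
        assert out["selection"].iloc[0] == "negative"

    def test_neutral_simulation_near_one(self, genome):
        assert _selection_run(genome, 1.0, 2000, seed=31) == \
            pytest.approx(1.0, abs=0.1)

    def test_purifying_simulation_recovers_acceptance(self, genome):
        assert _selection_run(genome, 0.2, 1500, seed=32) == \
            pytest.approx(0.2, abs=0.05)

    def test_neutral_deviation_shrinks_with_snv_count(self, genome):
        """|Ka/Ks - 1| shrinks in expectation as SNV count grows."""
        sizes = (500, 2000, 8000)
        devs = {n: [] for n in sizes}
        for seed in range(10):
            for n in sizes:
                devs[n].append(abs(_selection_run(genome, 1.0, n,
                                                  seed=100 + seed) - 1.0))
        means = [np.mean(devs[n]) for n in sizes]
        assert means[0] > means[1] > means[2]

    def test_unknown_environment_rejected(self):
        df = pd.DataFrame({"species_id": "sp", "sample_id": "s1",
                           "snv_class": ["synonymous"]})
        with pytest.raises(ValueError, match="environment"):
            sv.selection_pressure(df, {"sp": (1.0, 3.0)}, {"s1": "lunar"},
                                  {("sp", "s1"): 1.0})

    def test_class_proportions_sum_to_one(self, genome):
        pile, _ = sd.simulate_pileup(genome, 300, 0.35, 0.1, depth=40, seed=6)
        recs = sv.classify_snvs(sv.call_snvs(pile), genome.genes,
                                genome.contigs)
        classes = pd.Series([r.snv_class for r in recs]).value_counts(
            normalize=True)
        assert classes.sum() == pytest.approx(1.0)
        assert set(classes.index) <= {"synonymous", "nonsynonymous",
                                      "intergenic"}


class TestCogSelection:
    def test_single_cog_equals_genome_value(self, genome):
        mono_genes = [GeneRecord(g.gene_id, g.contig, g.start, g.end,
                                 g.strand, g.marker_id, g.ko, "J")
                      for g in genome.genes]
        mono = type(genome)(genome.bin_id, genome.contigs, mono_genes)
        pile, _ = sd.simulate_selection_pileup(mono, 800, 0.5, depth=50,
                                               seed=41)
        recs = sv.classify_snvs(sv.call_snvs(pile), mono.genes, mono.contigs)
        df = pd.DataFrame({
            "species_id": "sp", "sample_id": "s1",
            "snv_class": [r.snv_class for r in recs],
            "cog_category": [r.cog_category for r in recs]})
        out = sv.cog_selection(df, mono.genes, mono.contigs, {"s1": 50.0})
        sites = {"sp": sv.count_sites(mono.genes, mono.contigs)}
        genome_val = sv.selection_pressure(
            df, sites, {"s1": "dry"}, {("sp", "s1"): 50.0},
            method="pooled")["ka_ks"].iloc[0]
        assert out.loc[out["cog_category"] == "J", "ka_ks"].iloc[0] == \
            pytest.approx(genome_val)

    def test_no_synonymous_signal_undefined(self):
        contigs = {"c": "ATGTGGTGGTGGTAA"}  # Trp codons: no synonymous sites
        genes = [GeneRecord("g", "c", 0, 15, "+", cog="L")]
        df = pd.DataFrame({
            "species_id": "sp", "sample_id": "s1",
            "snv_class": ["nonsynonymous"] * 12,
            "cog_category": ["L"] * 12})
        out = sv.cog_selection(df, genes, contigs, {"s1": 10.0})
        assert np.isnan(out["ka_ks"].iloc[0])

    def test_planted_acceptance_contrast_ordering(self, small_species_set):
        genome = small_species_set.genomes["sp3"]
        half = len([g for g in genome.genes if g.marker_id is None]) // 2
        relabelled = []
        coding = [g for g in genome.genes if g.marker_id is None]
        for i, g in enumerate(coding):
            relabelled.append(GeneRecord(g.gene_id, g.contig, g.start, g.end,
                                         g.strand, None, g.ko,
                                         "J" if i < half else "L"))
        mono = type(genome)(genome.bin_id, genome.contigs, relabelled)
        j_genes = {g.gene_id for g in relabelled if g.cog == "J"}
        rows = []
        rng = np.random.default_rng(52)
        index = sv.GeneIndex(relabelled)
        # plant neutral SNVs in J genes, strongly purified ones in L genes
        for cog, accept in [("J", 1.0), ("L", 0.1)]:
            genes_c = [g for g in relabelled if g.cog == cog]
            placed = 0
            while placed < 400:
                g = genes_c[int(rng.integers(len(genes_c)))]
                pos = int(rng.integers(g.start, g.end))
                ref = mono.contigs[g.contig][pos]
                alt = "ACGT"[int(rng.integers(4))]
                if alt == ref:
                    continue
                cls = sv.classify_substitution(mono.contigs[g.contig],
                                               index.containing(g.contig, pos),
                                               pos, alt)
                if cls is None:
                    continue
                if cls == "nonsynonymous" and rng.random() > accept:
                    continue
                rows.append({"species_id": "sp", "sample_id": "s1",
                             "snv_class": cls, "cog_category": cog})
                placed += 1
        df = pd.DataFrame(rows)
        out = sv.cog_selection(df, relabelled, mono.contigs,
                               {"s1": 10.0}).set_index("cog_category")
        assert out.loc["L", "ka_ks"] < out.loc["J", "ka_ks"]
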