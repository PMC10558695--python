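"""Generator contracts: determinism, exact planting, self-consistent truth."""

import numpy as np
import pytest

from skincat import io as skio
from skincat import synthetic_data as sd
from skincat.snv_selection import GeneIndex, classify_substitution


class TestGenerateSpeciesSet:
    def test_single_species(self):
        sset = sd.generate_species_set(1, genome_length=15_000,
                                       n_genes_per_genome=8, seed=0,
                                       n_markers=5)
        assert set(sset.genomes) == {"sp1"}
        assert sset.truth.species_assignments == {"sp1": "sp1"}

    def test_seed_determinism_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            sset = sd.generate_species_set(2, genome_length=15_000,
                                           n_genes_per_genome=8, seed=42,
                                           n_markers=5)
            skio.write_bin(sset.genomes["sp1"], tmp_path / sub)
        assert (tmp_path / "a/sp1.fna").read_bytes() == \
            (tmp_path / "b/sp1.fna").read_bytes()
        assert (tmp_path / "a/sp1.gff3").read_bytes() == \
            (tmp_path / "b/sp1.gff3").read_bytes()

    def test_distinct_taxon_paths(self):
        sset = sd.generate_species_set(5, genome_length=15_000,
                                       n_genes_per_genome=8,
                                       taxon_tree_depth=3, seed=1, n_markers=5)
        paths = {g.taxon for g in sset.genomes.values()}
        assert len(paths) == 5
        assert all(len(p.split(";")) == 3 for p in paths)

    def test_genes_have_start_and_stop_codons(self, genome):
        for g in genome.genes:
            cds = genome.gene_sequence(g)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            prot = genome.protein(g)
            assert "*" not in prot

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sd.generate_species_set(1, genome_length=2_000,
                                    n_genes_per_genome=10, seed=0, n_markers=2)


class TestMutateToAni:
    def test_identity_preserved_at_ani_one(self, genome):
        m = sd.mutate_to_ani(genome, 1.0, seed=5, new_bin_id="x")
        assert sorted(s for s in m.contigs.values()) == \
            sorted(s for s in genome.contigs.values())

    def test_hamming_count_matches_target(self, genome):
        m = sd.mutate_to_ani(genome, 0.96, seed=5, new_bin_id="x")
        total = genome.total_length
        diffs = 0
        for old_name, new_name in zip(sorted(genome.contigs), sorted(m.contigs)):
            a, b = genome.contigs[old_name], m.contigs[new_name]
            diffs += sum(1 for x, y in zip(a, b) if x != y)
        assert diffs == round(0.04 * total)
        assert abs(diffs / total - 0.04) <= 0.002

    def test_gene_coordinates_preserved(self, genome):
        m = sd.mutate_to_ani(genome, 0.95, seed=6, new_bin_id="x")
        assert [(g.start, g.end, g.strand) for g in m.genes] == \
            [(g.start, g.end, g.strand) for g in genome.genes]


class TestSimulateCoverage:
    def _abundances(self):
        import pandas as pd
        return pd.DataFrame({"s1": [0.3, 0.7], "s2": [0.5, 0.5]},
                            index=["sp1", "sp2"])

    def test_zero_noise_gives_shared_exact_depth(self, small_species_set):
        cov = sd.simulate_coverage(self._abundances(),
                                   small_species_set.genomes,
                                   depth_scale=10, noise_cv=0.0, seed=0)
        for (sp, sample), expected in [(("sp1", "s1"), 3.0), (("sp2", "s2"), 5.0)]:
            contigs = set(small_species_set.genomes[sp].contigs)
            vals = cov[(cov["contig_id"].isin(contigs))
                       & (cov["sample_id"] == sample)]["depth"]
            assert (vals == expected).all()

    def test_zero_abundance_zero_depth(self, small_species_set):
        import pandas as pd
        ab = pd.DataFrame({"s1": [0.0, 1.0]}, index=["sp1", "sp2"])
        cov = sd.simulate_coverage(ab, small_species_set.genomes,
                                   noise_cv=0.2, seed=0)
        contigs = set(small_species_set.genomes["sp1"].contigs)
        assert (cov[cov["contig_id"].isin(contigs)]["depth"] == 0).all()


class TestSimulatePileup:
    def test_clean_pileup_without_snvs_or_errors(self, genome):
        pile, planted = sd.simulate_pileup(genome, 0, 0.0, 0.0, depth=20,
                                           error_rate=0.0, seed=1)
        assert planted == []
        counts = pile[["A", "C", "G", "T"]].to_numpy()
        assert (counts.sum(axis=1) == 20).all()
        ref_counts = counts[np.arange(len(pile)),
                            ["ACGT".index(b) for b in pile["ref"]]]
        assert (ref_counts == 20).all()

    def test_class_counts_match_targets(self, genome):
        _, planted = sd.simulate_pileup(genome, 400, 0.5, 0.1, depth=30,
                                        error_rate=0.0, seed=2)
        from collections import Counter
        c = Counter(p[4] for p in planted)
        assert c["nonsynonymous"] == 200
        assert c["intergenic"] == 40
        assert c["synonymous"] == 160

    def test_planted_classes_self_consistent(self, genome):
        """Re-classifying every planted SNV returns its planted class."""
        _, planted = sd.simulate_pileup(genome, 200, 0.35, 0.1, depth=30,
                                        seed=3)
        index = GeneIndex(genome.genes)
        for contig, pos, ref, alt, cls in planted:
            assert genome.contigs[contig][pos] == ref
            gene = index.containing(contig, pos)
            assert classify_substitution(genome.contigs[contig], gene,
                                         pos, alt) == cls

    def test_alt_counts_binomial(self, genome):
        pile, planted = sd.simulate_pileup(
            genome, 100, 0.3, 0.1, depth=100, alt_freq_range=(0.5, 0.5),
            error_rate=0.0, seed=4)
        by_site = pile.set_index(["contig_id", "pos"])
        alt_counts = np.array([by_site.loc[(c, pos + 1), alt]
                               for c, pos, _, alt, _ in planted])
        sigma = np.sqrt(100 * 0.25)
        # mean over 100 Binomial(100, 0.5) draws, plus rare tail outliers
        assert abs(alt_counts.mean() - 50) <= 3 * sigma / np.sqrt(len(planted))
        assert (np.abs(alt_counts - 50) > 3 * sigma).sum() <= 2

    def test_bad_targets_rejected(self, genome):
        with pytest.raises(ValueError, match="sum"):
            sd.simulate_pileup(genome, 10, 0.8, 0.4, seed=0)


class TestPlantHgt:
    def test_zero_divergence_identical_copy(self, small_species_set):
        donor = small_species_set.genomes["sp1"]
        recipient = small_species_set.genomes["sp2"]
        gene = next(g for g in donor.genes if g.marker_id is None)
        new_bin, entry = sd.plant_hgt(donor, recipient, gene.gene_id, 0.0,
                                      seed=1)
        moved = next(g for g in new_bin.genes
                     if g.gene_id == entry[2])
        assert new_bin.contigs[moved.contig][moved.start:moved.end] == \
            donor.contigs[gene.contig][gene.start:gene.end]

    def test_divergence_fraction_realised(self, small_species_set):
        donor = small_species_set.genomes["sp1"]
        recipient = small_species_set.genomes["sp2"]
        gene = next(g for g in donor.genes if g.marker_id is None)
        new_bin, entry = sd.plant_hgt(donor, recipient, gene.gene_id, 0.05,
                                      seed=2)
        moved = next(g for g in new_bin.genes if g.gene_id == entry[2])
        a = donor.contigs[gene.contig][gene.start:gene.end]
        b = new_bin.contigs[moved.contig][moved.start:moved.end]
        diffs = sum(1 for x, y in zip(a, b) if x != y)
        assert diffs == round(0.05 * len(a))

    def test_existing_recipient_genes_untouched(self, small_species_set):
        donor = small_species_set.genomes["sp1"]
        recipient = small_species_set.genomes["sp2"]
        gene = next(g for g in donor.genes if g.marker_id is None)
        new_bin, _ = sd.plant_hgt(donor, recipient, gene.gene_id, 0.01, seed=3)
        for g in recipient.genes:
            assert new_bin.contigs[g.contig][g.start:g.end] == \
                recipient.contigs[g.contig][g.start:g.end]
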