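"""Best-match HGT detection, recency split, and COG contrast."""

import numpy as np
import pytest

from skincat import hgt_detection as hgt
from skincat import synthetic_data as sd
from skincat.hgt_detection import HGTEvent, classify_recency


class TestClassifyRecency:
    @pytest.mark.parametrize("identity,expected", [
        (0.995, "recent"),
        (0.99, "non_recent"),   # divergence exactly 0.01: strict threshold
        (0.95, "non_recent"),
    ])
    def test_threshold(self, identity, expected):
        assert classify_recency(1.0 - identity) == expected


def _scenario(seed, divergence=0.005, n_transfers=2):
    return sd.simulate_hgt_scenario(
        n_species_per_group=2, n_groups=2, n_transfers=n_transfers,
        divergence=divergence, genome_length=20_000, n_genes_per_genome=12,
        n_markers=5, seed=seed)


class TestDetectCandidates:
    def test_no_plants_no_candidates(self):
        sset = sd.generate_species_set(4, genome_length=15_000,
                                       n_genes_per_genome=8, seed=61,
                                       n_markers=5, n_top_groups=2)
        events = hgt.detect_candidates(list(sset.genomes.values()))
        assert events == []

    def test_planted_transfer_recovered_with_orientation(self):
        bins, truth = _scenario(seed=62, n_transfers=1)
        events = hgt.detect_candidates(bins)
        assert len(events) == 1
        donor, recipient, gene_id, div = truth.planted_hgts[0]
        e = events[0]
        assert e.recipient_genome == recipient
        assert e.donor_genome in (donor, f"{donor}b")
        assert e.recency == "recent"
        assert e.orientation == "resolved"

    def test_vertical_gene_not_flagged(self):
        """A gene more similar within-group than cross-group stays silent."""
        sset = sd.generate_species_set(2, genome_length=15_000,
                                       n_genes_per_genome=8, seed=63,
                                       n_markers=5, n_top_groups=2)
        sp1, sp2 = sset.genomes["sp1"], sset.genomes["sp2"]
        gene = next(g for g in sp1.genes if g.marker_id is None)
        # same gene in both groups, but the within-group copy is closer
        sp2_mod, _ = sd.plant_hgt(sp1, sp2, gene.gene_id, 0.08, seed=1)
        sibling = sd.mutate_to_ani(sp1, 0.99, seed=2, new_bin_id="sp1b")
        events = hgt.detect_candidates([sp1, sibling, sp2_mod])
        flagged_native = [e for e in events
                          if gene.gene_id in (e.gene_id, e.donor_gene_id)
                          and e.recipient_genome in ("sp1", "sp1b")]
        assert flagged_native == []

    def test_single_group_rejected(self):
        sset = sd.generate_species_set(2, genome_length=15_000,
                                       n_genes_per_genome=8, seed=64,
                                       n_markers=5, n_top_groups=1)
        with pytest.raises(ValueError, match="two taxon groups"):
            hgt.detect_candidates(list(sset.genomes.values()))

    def test_order_invariance(self):
        bins, _ = _scenario(seed=65)
        fwd = hgt.detect_candidates(bins)
        rev = hgt.detect_candidates(list(reversed(bins)))
        key = lambda e: (e.gene_id, e.donor_genome, e.recipient_genome)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_reported_recency_consistent_with_divergence(self):
        bins, _ = _scenario(seed=66, divergence=(0.005, 0.05))
        for e in hgt.detect_candidates(bins):
            assert e.recency == classify_recency(e.divergence)
            assert e.donor_taxon != e.recipient_taxon


class TestValidatePhylogeny:
    def test_planted_transfer_validated(self):
        # two siblings per species give the gene tree enough donor tips to
        # show the recipient nesting inside the donor clade
        bins, truth = sd.simulate_hgt_scenario(
            n_species_per_group=2, n_groups=2, n_transfers=1,
            divergence=0.005, genome_length=20_000, n_genes_per_genome=12,
            n_markers=5, n_siblings=2, seed=67)
        events = hgt.detect_candidates(bins)
        assert len(events) == 1
        out = hgt.validate_phylogeny(events[0], bins)
        assert out.validation == "validated"

    def test_clocklike_vertical_signal_rejected(self):
        """A gene family inherited vertically by the recipient's relatives
        keeps the recipient with its own clade and is not validated."""
        sset = sd.generate_species_set(4, genome_length=20_000,
                                       n_genes_per_genome=12, seed=69,
                                       n_markers=5, n_top_groups=2)
        sp1 = sset.genomes["sp1"]
        gene = next(g for g in sp1.genes if g.marker_id is None)
        # distant homolog established in both group-2 species, then
        # inherited by all their descendant strains
        sset.genomes["sp2"], entry = sd.plant_hgt(
            sp1, sset.genomes["sp2"], gene.gene_id, 0.25, seed=1)
        sset.genomes["sp4"], _ = sd.plant_hgt(
            sp1, sset.genomes["sp4"], gene.gene_id, 0.25, seed=2)
        bins = []
        for i, (sp, g) in enumerate(sorted(sset.genomes.items())):
            bins.append(g)
            for si, suf in enumerate("bc"):
                bins.append(sd.mutate_to_ani(g, 0.98, seed=100 + 10 * i + si,
                                             new_bin_id=f"{sp}{suf}"))
        event = HGTEvent(entry[2], "sp1", "sp2", "P1", "P2",
                         identity=0.75, divergence=0.25, recency="non_recent")
        out = hgt.validate_phylogeny(event, bins)
        assert out.validation == "rejected"

    def test_two_genome_input_unvalidated(self):
        sset = sd.generate_species_set(2, genome_length=15_000,
                                       n_genes_per_genome=8, seed=68,
                                       n_markers=5, n_top_groups=2)
        sp1, sp2 = sset.genomes["sp1"], sset.genomes["sp2"]
        gene = next(g for g in sp1.genes if g.marker_id is None)
        sp2_mod, entry = sd.plant_hgt(sp1, sp2, gene.gene_id, 0.005, seed=1)
        events = hgt.detect_candidates([sp1, sp2_mod])
        assert len(events) == 1
        out = hgt.validate_phylogeny(events[0], [sp1, sp2_mod])
        assert out.validation == "unvalidated"


def _event(recency, cog):
    return HGTEvent("g", "a", "b", "P1", "P2", 0.99, 0.01, recency,
                    cog_category=cog)


class TestCogContrast:
    def test_identical_composition_no_signal(self):
        events = ([_event("recent", "J") for _ in range(10)]
                  + [_event("recent", "L") for _ in range(10)]
                  + [_event("non_recent", "J") for _ in range(10)]
                  + [_event("non_recent", "L") for _ in range(10)])
        out = hgt.cog_contrast(events)
        assert (out["odds_ratio"] == 1.0).all()
        assert not (out["q_value"] <= 0.05).any()

    def test_planted_enrichment_ranks_first(self):
        rng = np.random.default_rng(0)
        events = []
        for _ in range(100):  # recent: L-rich over a J/K background
            r = rng.random()
            events.append(_event("recent",
                                 "L" if r < 0.5 else ("J" if r < 0.75 else "K")))
        for _ in range(100):  # non-recent: L-poor
            r = rng.random()
            events.append(_event("non_recent",
                                 "L" if r < 0.1 else ("J" if r < 0.55 else "K")))
        out = hgt.cog_contrast(events)
        assert out.iloc[0]["cog_category"] == "L"
        assert out.iloc[0]["q_value"] <= 0.05
        assert out.iloc[0]["odds_ratio"] > 1

    def test_absent_cog_omitted(self):
        events = [_event("recent", "J"), _event("non_recent", "J")]
        out = hgt.cog_contrast(events)
        assert out["cog_category"].tolist() == ["J"]
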