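"""End-to-end orchestration: simulate -> qc -> derep -> abundance ->
function -> snv -> hgt -> bgcnet.

Each stage reads its inputs from the run directory and writes TSV/FASTA
outputs there, so stages can be rerun individually; a manifest records
parameters, the seed, and a checksum per output.  A run with the same
configuration and seed reproduces byte-identical outputs.

Default thresholds mirror the catalog-building procedure: HQ/MQ tiers at
0.90/0.05 and 0.50/0.10, species clustering at ANI 0.95 with alignment
fraction 0.30, SNV filters depth 5 / frequency 0.05 / FDR 1e-6, HGT
recency below 0.01 divergence, protein families at 0.5 identity and 0.9
coverage, family assignment at 0.3 alignment coverage, and BGC gene
sharing at 0.5/0.5.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import bgc_network as bn
from . import dereplication as dr
from . import functional_profiling as fp
from . import genome_qc as qc
from . import hgt_detection as hgt
from . import io as skio
from . import snv_selection as sv
from . import synthetic_data as sd

logger = logging.getLogger("skincat")

STAGES = ["simulate", "qc", "derep", "abundance", "function", "snv", "hgt", "bgcnet"]

STAGE_DEPS = {
    "simulate": [],
    "qc": ["simulate"],
    "derep": ["qc"],
    "abundance": ["derep"],
    "function": ["derep"],
    "snv": ["derep"],
    "hgt": ["derep"],
    "bgcnet": ["simulate"],
}

# markers that a stage has completed, used to check dependencies of
# partially rerun pipelines
STAGE_SENTINELS = {
    "simulate": "truth.json",
    "qc": "qc.tsv",
    "derep": "clusters.tsv",
    "abundance": "abundance.tsv",
    "function": "module_completeness.tsv",
    "snv": "selection.tsv",
    "hgt": "hgt_events.tsv",
    "bgcnet": "bgc_components.tsv",
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {
        "n_species": 4,
        "n_top_groups": 2,
        "genome_length": 30_000,
        "n_genes_per_genome": 20,
        "n_markers": 20,
        "bins_per_species": 2,
        "bin_qualities": [[1.0, 0.0], [0.9, 0.05], [0.75, 0.08]],
        "within_species_ani": [0.985, 0.999],
        "n_samples": 6,
        "environments": ["sebaceous", "moist", "dry"],
        "depth_scale": 30.0,
        "noise_cv": 0.1,
        "n_hgt": 2,
        "hgt_divergence": 0.005,
        "snv_species": 2,
        "snvs_per_sample": 300,
        "snv_depth": 50,
        "env_nonsyn_acceptance": {"sebaceous": 0.9, "moist": 0.6, "dry": 0.3},
        "reads_per_sample": 100,
        "read_length": 120,
        "unknown_read_fraction": 0.2,
        "bgc_families": 2,
        "bgcs_per_family": 3,
        "bgc_genes": 4,
        "bgc_singletons": 2,
    },
    "qc": {"hq": [0.90, 0.05], "mq": [0.50, 0.10]},
    "derep": {"ani_threshold": 0.95, "af_threshold": 0.30, "fragment_length": 1000},
    "abundance": {"k": 31, "min_containment": 0.6},
    "function": {"min_id": 0.5, "min_cov": 0.9, "min_aln_cov": 0.30},
    "snv": {"min_depth": 5, "min_freq": 0.05, "fdr": 1e-6, "error_rate": 0.001},
    "hgt": {"min_identity": 0.9, "recency_threshold": 0.01, "rank": 0,
            "validate": True},
    "bgcnet": {"min_cov": 0.5, "min_id": 0.5, "min_shared": 1},
}

MODULE_DEFINITIONS = [
    ("M001", "K00001 K00002 K00003"),
    ("M002", "K00004 (K00005,K00006)"),
    ("M003", "K00007+K00008 K00009"),
    ("M004", "(K00010,K00011) K00012 -K00099"),
    ("M005", "K00013 K00014 (K00015,K00016+K00017)"),
]


def load_config(path: str | None = None, seed: int | None = None,
                overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user)
    if overrides:
        _merge(cfg, overrides)
    if seed is not None:
        cfg["seed"] = seed
    _validate(cfg)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def _validate(cfg: dict) -> None:
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    for key, lo, hi in [
        (("derep", "ani_threshold"), 0, 1),
        (("derep", "af_threshold"), 0, 1),
        (("snv", "min_freq"), 0, 1),
        (("hgt", "min_identity"), 0, 1),
        (("hgt", "recency_threshold"), 0, 1),
        (("bgcnet", "min_cov"), 0, 1),
        (("bgcnet", "min_id"), 0, 1),
    ]:
        val = cfg[key[0]][key[1]]
        if not (lo <= val <= hi):
            raise ValueError(f"{'.'.join(key)} = {val} outside [{lo}, {hi}]")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["simulate"]
    seed = cfg["seed"]
    rng = np.random.default_rng(seed)
    sset = sd.generate_species_set(
        n_species=p["n_species"],
        genome_length=p["genome_length"],
        n_genes_per_genome=p["n_genes_per_genome"],
        seed=seed,
        n_markers=p["n_markers"],
        n_top_groups=p["n_top_groups"],
    )
    truth = sset.truth
    species = sorted(sset.genomes)

    # plant cross-group transfers into reference genomes before binning
    groups: dict[str, list[str]] = {}
    for sp in species:
        groups.setdefault(sset.genomes[sp].taxon.split(";")[0], []).append(sp)
    gnames = sorted(groups)
    if len(gnames) >= 2 and p["n_hgt"] > 0:
        donors, recipients = groups[gnames[0]], groups[gnames[1]]
        pool = [(spd, g.gene_id) for spd in donors
                for g in sset.genomes[spd].genes if g.marker_id is None]
        picks = rng.choice(len(pool), size=min(p["n_hgt"], len(pool)),
                           replace=False)
        for i, idx in enumerate(sorted(picks)):
            spd, gid = pool[int(idx)]
            spr = recipients[i % len(recipients)]
            sset.genomes[spr], entry = sd.plant_hgt(
                sset.genomes[spd], sset.genomes[spr], gid,
                p["hgt_divergence"], seed=int(rng.integers(2**31)))
            truth.planted_hgts.append(entry)

    refdir = outdir / "refs"
    bindir = outdir / "bins"
    for sp in species:
        skio.write_bin(sset.genomes[sp], refdir)

    # degraded bins per species at controlled within-species ANI
    qualities = p["bin_qualities"]
    bin_rows = []
    for si, sp in enumerate(species):
        others = [sset.genomes[s] for s in species if s != sp]
        for bi in range(p["bins_per_species"]):
            ani = float(rng.uniform(*p["within_species_ani"]))
            mutated = sd.mutate_to_ani(sset.genomes[sp], ani,
                                       seed=int(rng.integers(2**31)),
                                       new_bin_id=f"{sp}tmp")
            comp, cont = qualities[(si * p["bins_per_species"] + bi) % len(qualities)]
            b = sd.make_bin(mutated, comp, cont, others, sset.marker_set,
                            seed=int(rng.integers(2**31)),
                            bin_id=f"{sp}_b{bi + 1}")
            b.taxon = sset.genomes[sp].taxon
            skio.write_bin(b, bindir)
            truth.species_assignments[b.bin_id] = sp
            bin_rows.append({"bin_id": b.bin_id, "species_id": sp,
                             "taxon": b.taxon})
    bins_df = pd.DataFrame(bin_rows)
    _write_tsv(bins_df, outdir / "bin_table.tsv")

    # sample metadata and true abundances
    samples = [f"s{i + 1}" for i in range(p["n_samples"])]
    envs = [p["environments"][i % len(p["environments"])]
            for i in range(p["n_samples"])]
    _write_tsv(pd.DataFrame({"sample_id": samples, "environment": envs}),
               outdir / "samples.tsv")
    ab_matrix = rng.dirichlet(np.ones(len(species)) * 2.0, size=len(samples)).T
    abundances = pd.DataFrame(ab_matrix, index=species, columns=samples)
    truth.true_abundances = abundances
    cov = sd.simulate_coverage(abundances, sset.genomes,
                               depth_scale=p["depth_scale"],
                               noise_cv=p["noise_cv"],
                               seed=int(rng.integers(2**31)))
    skio.write_coverage(cov, outdir / "coverage.tsv")

    # per-sample pileups under environment-specific selection
    piledir = outdir / "pileups"
    piledir.mkdir(parents=True, exist_ok=True)
    for sp in species[: p["snv_species"]]:
        for sample, env in zip(samples, envs):
            accept = p["env_nonsyn_acceptance"][env]
            pile, planted = sd.simulate_selection_pileup(
                sset.genomes[sp], p["snvs_per_sample"],
                nonsyn_acceptance=accept, depth=p["snv_depth"],
                seed=int(rng.integers(2**31)))
            skio.write_pileup(pile, piledir / f"{sp}__{sample}.tsv")
            truth.planted_snvs.extend(
                (c, pos, ref, alt, cls) for c, pos, ref, alt, cls in planted)

    # reads for the classification-rate statistic
    readdir = outdir / "reads"
    readdir.mkdir(parents=True, exist_ok=True)
    for sample in samples:
        reads = {}
        for ri in range(p["reads_per_sample"]):
            rid = f"{sample}_r{ri + 1}"
            if rng.random() < p["unknown_read_fraction"]:
                reads[rid] = sd._random_dna(rng, p["read_length"])
            else:
                sp = species[int(rng.integers(len(species)))]
                contigs = sorted(sset.genomes[sp].contigs)
                big = max(contigs,
                          key=lambda c: len(sset.genomes[sp].contigs[c]))
                seq = sset.genomes[sp].contigs[big]
                start = int(rng.integers(0, len(seq) - p["read_length"]))
                reads[rid] = seq[start : start + p["read_length"]]
        skio.write_fasta(reads, readdir / f"{sample}.fasta")

    # BGCs with planted shared genes
    taxa = {sp: sset.genomes[sp].taxon for sp in species}
    bgcs, shared = sd.simulate_bgcs(
        n_families=p["bgc_families"], bgcs_per_family=p["bgcs_per_family"],
        genes_per_bgc=p["bgc_genes"], n_singletons=p["bgc_singletons"],
        genome_taxa=taxa, seed=int(rng.integers(2**31)))
    truth.shared_bgc_genes = shared
    bgc_rows = []
    bgc_seqs = {}
    for b in bgcs:
        for gid, seq in sorted(b.genes.items()):
            bgc_rows.append({"bgc_id": b.bgc_id, "genome_id": b.genome_id,
                             "product_class": b.product_class, "gene_id": gid})
            bgc_seqs[gid] = seq
    _write_tsv(pd.DataFrame(bgc_rows), outdir / "bgc_genes.tsv")
    skio.write_fasta(bgc_seqs, outdir / "bgc_proteins.faa")

    _write_tsv(pd.DataFrame([{"module_id": m, "definition": d}
                             for m, d in MODULE_DEFINITIONS]),
               outdir / "modules.tsv")
    (outdir / "markers.txt").write_text(
        "\n".join(sset.marker_set.marker_ids) + "\n")
    _write_tsv(pd.DataFrame([{"species_id": sp, "taxon": taxa[sp]}
                             for sp in species]), outdir / "taxa.tsv")

    truth_json = {
        "seed": truth.seed,
        "species_assignments": truth.species_assignments,
        "true_abundances": {s: {sp: float(abundances.loc[sp, s])
                                for sp in species} for s in samples},
        "planted_snvs": [list(t) for t in truth.planted_snvs],
        "planted_hgts": [list(t) for t in truth.planted_hgts],
        "shared_bgc_genes": [[a, b, list(pair)]
                             for a, b, pair in truth.shared_bgc_genes],
    }
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1,
                                                  sort_keys=True) + "\n")
    out = [outdir / "truth.json", outdir / "coverage.tsv",
           outdir / "samples.tsv", outdir / "bin_table.tsv",
           outdir / "bgc_genes.tsv", outdir / "bgc_proteins.faa",
           outdir / "modules.tsv", outdir / "markers.txt", outdir / "taxa.tsv"]
    out += sorted(refdir.glob("*")) + sorted(bindir.glob("*"))
    out += sorted(piledir.glob("*")) + sorted(readdir.glob("*"))
    return out


def _load_bins(outdir: Path) -> list[qc.GenomeBin]:
    table = pd.read_csv(outdir / "bin_table.tsv", sep="\t")
    bins = []
    for _, row in table.iterrows():
        bins.append(skio.read_bin(row["bin_id"], outdir / "bins",
                                  taxon=row["taxon"]))
    return bins


def _load_marker_set(outdir: Path) -> qc.MarkerSet:
    ids = (outdir / "markers.txt").read_text().split()
    return qc.MarkerSet(tuple(ids))


def stage_qc(cfg: dict, outdir: Path) -> list[Path]:
    bins = _load_bins(outdir)
    markers = _load_marker_set(outdir)
    rows = []
    for b in qc.qc_report(bins, markers):
        rows.append({"bin_id": b.bin_id, "completeness": b.completeness,
                     "contamination": b.contamination, "tier": b.tier})
    _write_tsv(pd.DataFrame(rows).sort_values("bin_id"), outdir / "qc.tsv")
    return [outdir / "qc.tsv"]


def stage_derep(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["derep"]
    bins = _load_bins(outdir)
    qdf = pd.read_csv(outdir / "qc.tsv", sep="\t").set_index("bin_id")
    for b in bins:
        b.completeness = float(qdf.loc[b.bin_id, "completeness"])
        b.contamination = float(qdf.loc[b.bin_id, "contamination"])
        b.tier = str(qdf.loc[b.bin_id, "tier"])
    cache: dict = {}
    clusters = dr.cluster_genomes(bins, ani_threshold=p["ani_threshold"],
                                  af_threshold=p["af_threshold"],
                                  fragment_length=p["fragment_length"],
                                  ani_cache=cache)
    rows = []
    for c in clusters:
        for m in sorted(c.member_ids):
            rows.append({"cluster_id": c.cluster_id, "member": m,
                         "is_representative": m == c.representative_id})
    _write_tsv(pd.DataFrame(rows), outdir / "clusters.tsv")
    ani_rows = [{"genome_a": min(r.genome_a, r.genome_b),
                 "genome_b": max(r.genome_a, r.genome_b),
                 "ani": r.ani, "af": r.af} for r in cache.values()]
    _write_tsv(pd.DataFrame(ani_rows).sort_values(["genome_a", "genome_b"]),
               outdir / "ani.tsv")
    repdir = outdir / "representatives"
    by_id = {b.bin_id: b for b in bins}
    for c in clusters:
        skio.write_bin(by_id[c.representative_id], repdir)
    reps = pd.DataFrame([
        {"cluster_id": c.cluster_id, "representative": c.representative_id}
        for c in clusters])
    _write_tsv(reps, outdir / "representatives.tsv")
    return [outdir / "clusters.tsv", outdir / "ani.tsv",
            outdir / "representatives.tsv"] + sorted(repdir.glob("*"))


def _load_clusters(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "clusters.tsv", sep="\t")


def stage_abundance(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["abundance"]
    cov = skio.read_coverage(outdir / "coverage.tsv")
    normalized = ab.normalize_depths(cov)
    clusters = _load_clusters(outdir)
    bins = {b.bin_id: b for b in _load_bins(outdir)}
    refs_avail = {f.stem for f in (outdir / "refs").glob("*.fna")}
    species_contigs: dict[str, list[str]] = {}
    for cid, grp in clusters.groupby("cluster_id"):
        contigs: list[str] = []
        for m in grp["member"]:
            contigs.extend(bins[m].contigs)
            # the coverage table is keyed by reference contigs; include the
            # member species' reference contigs as well
        species_contigs[cid] = contigs
    ref_bins = {r: skio.read_bin(r, outdir / "refs") for r in sorted(refs_avail)}
    truth_assign = pd.read_csv(outdir / "bin_table.tsv", sep="\t")
    member_species = dict(zip(truth_assign["bin_id"], truth_assign["species_id"]))
    for cid, grp in clusters.groupby("cluster_id"):
        for m in grp["member"]:
            sp = member_species.get(m)
            if sp in ref_bins:
                species_contigs[cid].extend(ref_bins[sp].contigs)
    species_contigs = {cid: sorted(set(c)) for cid, c in species_contigs.items()}
    profile = ab.species_abundance(normalized, species_contigs)
    out = profile.reset_index().rename(columns={"index": "species_id"})
    _write_tsv(out, outdir / "abundance.tsv")

    reps = pd.read_csv(outdir / "representatives.tsv", sep="\t")
    rep_bins = [skio.read_bin(r, outdir / "representatives")
                for r in reps["representative"]]
    rate_rows = []
    for fa in sorted((outdir / "reads").glob("*.fasta")):
        reads = list(skio.read_fasta(fa).values())
        rate = ab.classification_rate(reads, rep_bins, k=p["k"],
                                      min_containment=p["min_containment"])
        rate_rows.append({"sample_id": fa.stem, "classified_fraction": rate})
    _write_tsv(pd.DataFrame(rate_rows), outdir / "classification.tsv")
    return [outdir / "abundance.tsv", outdir / "classification.tsv"]


def stage_function(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["function"]
    reps = pd.read_csv(outdir / "representatives.tsv", sep="\t")
    rep_bins = [skio.read_bin(r, outdir / "representatives")
                for r in reps["representative"]]
    proteins: dict[str, str] = {}
    ko_by_bin: dict[str, set[str]] = {}
    for b in rep_bins:
        kos = set()
        for g in b.genes:
            if g.marker_id is not None:
                continue
            proteins[f"{b.bin_id}|{g.gene_id}"] = b.protein(g)
            if g.ko:
                kos.add(g.ko)
        ko_by_bin[b.bin_id] = kos
    families = fp.cluster_proteins(proteins, min_id=p["min_id"],
                                   min_cov=p["min_cov"])
    fam_rows = []
    for fam in families:
        for m in sorted(fam.member_proteins):
            fam_rows.append({"family_id": fam.family_id, "protein_id": m,
                             "is_representative":
                                 m == fam.representative_protein})
    _write_tsv(pd.DataFrame(fam_rows), outdir / "protein_families.tsv")

    modules = pd.read_csv(outdir / "modules.tsv", sep="\t")
    mc_rows = []
    for b in sorted(ko_by_bin):
        for _, mrow in modules.iterrows():
            mdef = fp.parse_module_definition(mrow["module_id"],
                                              mrow["definition"])
            mc_rows.append({
                "genome": b, "module_id": mrow["module_id"],
                "completeness": fp.module_completeness(ko_by_bin[b], mdef)})
    _write_tsv(pd.DataFrame(mc_rows), outdir / "module_completeness.tsv")
    return [outdir / "protein_families.tsv", outdir / "module_completeness.tsv"]


def stage_snv(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["snv"]
    samples = pd.read_csv(outdir / "samples.tsv", sep="\t")
    env = dict(zip(samples["sample_id"], samples["environment"]))
    snv_rows = []
    depth_map: dict[tuple[str, str], float] = {}
    sites: dict[str, tuple[float, float]] = {}
    for pf in sorted((outdir / "pileups").glob("*.tsv")):
        species, sample = pf.stem.split("__")
        ref = skio.read_bin(species, outdir / "refs")
        pile = skio.read_pileup(pf)
        recs = sv.call_snvs(pile, min_depth=p["min_depth"],
                            min_freq=p["min_freq"], fdr=p["fdr"],
                            error_rate=p["error_rate"])
        recs = sv.classify_snvs(recs, ref.genes, ref.contigs)
        depth = pile[["A", "C", "G", "T"]].to_numpy().sum(axis=1)
        depth_map[(species, sample)] = float(depth[depth > 0].mean())
        if species not in sites:
            sites[species] = sv.count_sites(ref.genes, ref.contigs)
        for r in recs:
            snv_rows.append({
                "species_id": species, "sample_id": sample,
                "CHROM": r.contig, "POS": r.position + 1, "REF": r.ref,
                "ALT": r.alt, "DP": r.depth, "AF": r.alt_freq,
                "CLASS": r.snv_class, "gene_id": r.gene_id,
                "cog_category": r.cog_category})
    snv_df = pd.DataFrame(snv_rows)
    _write_tsv(snv_df, outdir / "snvs.tsv")
    sel = sv.selection_pressure(
        snv_df.rename(columns={"CLASS": "snv_class"}),
        sites, env, depth_map)
    _write_tsv(sel, outdir / "selection.tsv")
    cog_frames = []
    for species in sorted({s for s, _ in depth_map}):
        ref = skio.read_bin(species, outdir / "refs")
        sub = snv_df[snv_df["species_id"] == species].rename(
            columns={"CLASS": "snv_class"})
        depths = {smp: depth_map[(species, smp)]
                  for smp in sub["sample_id"].unique()}
        cdf = sv.cog_selection(sub, ref.genes, ref.contigs, depths)
        cdf.insert(0, "species_id", species)
        cog_frames.append(cdf)
    _write_tsv(pd.concat(cog_frames, ignore_index=True)
               if cog_frames else pd.DataFrame(), outdir / "cog_selection.tsv")
    return [outdir / "snvs.tsv", outdir / "selection.tsv",
            outdir / "cog_selection.tsv"]


def stage_hgt(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["hgt"]
    reps = pd.read_csv(outdir / "representatives.tsv", sep="\t")
    taxa = pd.read_csv(outdir / "taxa.tsv", sep="\t")
    bin_table = pd.read_csv(outdir / "bin_table.tsv", sep="\t")
    sp_taxon = dict(zip(taxa["species_id"], taxa["taxon"]))
    member_species = dict(zip(bin_table["bin_id"], bin_table["species_id"]))
    # HGT screening runs on the species representatives, as catalog
    # analyses do; their taxon comes from their source species
    rep_bins = []
    for r in reps["representative"]:
        b = skio.read_bin(r, outdir / "representatives",
                          taxon=sp_taxon.get(member_species.get(r, r)))
        rep_bins.append(b)
    events = hgt.detect_candidates(rep_bins, rank=p["rank"],
                                   min_identity=p["min_identity"])
    if p.get("validate", True):
        events = [hgt.validate_phylogeny(e, rep_bins, rank=p["rank"])
                  for e in events]
    rows = [{
        "gene_id": e.gene_id, "donor": e.donor_genome,
        "recipient": e.recipient_genome, "donor_taxon": e.donor_taxon,
        "recipient_taxon": e.recipient_taxon, "identity": e.identity,
        "divergence": e.divergence, "recency": e.recency,
        "cog": e.cog_category or "", "orientation": e.orientation,
        "validation": e.validation,
    } for e in events]
    _write_tsv(pd.DataFrame(rows, columns=[
        "gene_id", "donor", "recipient", "donor_taxon", "recipient_taxon",
        "identity", "divergence", "recency", "cog", "orientation",
        "validation"]), outdir / "hgt_events.tsv")
    contrast = hgt.cog_contrast(events)
    _write_tsv(contrast, outdir / "hgt_cog_contrast.tsv")
    return [outdir / "hgt_events.tsv", outdir / "hgt_cog_contrast.tsv"]


def stage_bgcnet(cfg: dict, outdir: Path) -> list[Path]:
    p = cfg["bgcnet"]
    table = pd.read_csv(outdir / "bgc_genes.tsv", sep="\t")
    seqs = skio.read_fasta(outdir / "bgc_proteins.faa")
    taxa = pd.read_csv(outdir / "taxa.tsv", sep="\t")
    genome_taxa = dict(zip(taxa["species_id"], taxa["taxon"]))
    bgcs = []
    for bgc_id, grp in table.groupby("bgc_id", sort=True):
        bgcs.append(bn.BGCRecord(
            bgc_id=bgc_id,
            genome_id=grp["genome_id"].iloc[0],
            product_class=grp["product_class"].iloc[0],
            genes={g: seqs[g] for g in grp["gene_id"]}))
    net = bn.build_network(bgcs, min_shared=p["min_shared"],
                           min_cov=p["min_cov"], min_id=p["min_id"])
    edge_rows = [{
        "bgc_a": min(a, b), "bgc_b": max(a, b),
        "shared_gene_count": d["shared_gene_count"],
        "mean_identity": d["mean_identity"],
    } for a, b, d in net.graph.edges(data=True)]
    _write_tsv(pd.DataFrame(edge_rows, columns=[
        "bgc_a", "bgc_b", "shared_gene_count", "mean_identity"]).sort_values(
            ["bgc_a", "bgc_b"]) if edge_rows else pd.DataFrame(
            columns=["bgc_a", "bgc_b", "shared_gene_count", "mean_identity"]),
        outdir / "bgc_edges.tsv")
    summary = bn.subnet_summary(net, bgcs, genome_taxa)
    _write_tsv(summary, outdir / "bgc_components.tsv")
    nx_path = outdir / "bgc_network.graphml"
    import networkx as nx
    nx.write_graphml(net.graph, nx_path)
    return [outdir / "bgc_edges.tsv", outdir / "bgc_components.tsv", nx_path]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "derep": stage_derep,
    "abundance": stage_abundance,
    "function": stage_function,
    "snv": stage_snv,
    "hgt": stage_hgt,
    "bgcnet": stage_bgcnet,
}


def run(config: dict, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order; return the manifest.

    Raises if an enabled stage's dependency is neither enabled nor already
    completed in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config["stages"]]
    for stage in enabled:
        for dep in STAGE_DEPS[stage]:
            if dep not in enabled and not (outdir / STAGE_SENTINELS[dep]).exists():
                raise ValueError(
                    f"stage {stage!r} requires {dep!r}, which is neither "
                    f"enabled nor already complete in {outdir}")
    manifest: dict = {"seed": config["seed"], "parameters": config,
                      "stages": {}}
    for stage in enabled:
        logger.info("running stage %s", stage)
        outputs = _STAGE_FUNCS[stage](config, outdir)
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(outdir)): _sha256(p)
                        for p in sorted(outputs)}}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
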