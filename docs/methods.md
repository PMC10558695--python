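# Methods

`skincat` reimplements, at desk scale and with exact ground truth, the
computational core of large skin-metagenome catalog studies: genome-bin
quality tiering, ANI-based species dereplication, coverage-based abundance,
SNV-based selection-pressure profiling across skin environments,
best-match horizontal gene transfer (HGT) detection with a recency split,
KEGG-module completeness, and shared-gene biosynthetic-cluster (BGC)
networks. This note records the models, the parameters that matter, the
synthetic data the pipeline is exercised on, and the design choices made
where the procedure was genuinely open.

## Sequence primitives

All comparisons run through one seed-and-extend aligner
(`seqcore.align_pair`). Two sequences are alignable only if they share an
exact k-mer (k = 15 for DNA, 5 for protein); extension is full affine-gap
dynamic programming (Biopython's `PairwiseAligner`) on a diagonal window of
±32 around the densest seed diagonal. Scoring is match/mismatch 2/−3 with
gap open/extend −5/−2 for DNA and BLOSUM62 with −11/−1 for protein —
conventional defaults; every downstream decision is thresholded, so only
relative ordering matters. Identity is computed over aligned columns with
internal gap columns counted as mismatches (conservative and unambiguous);
terminal subject overhang in glocal mode is free and excluded. For
sequences short enough to fall inside the window the reported score is the
exact optimum, which the test suite checks against an independent
Smith–Waterman–Gotoh implementation.

Translation uses the bacterial code (table 11); codons containing any
ambiguity code translate to `X` and are excluded from both SNV
classification and site counting.

## Genome quality and tiers

Completeness and contamination come from a designated set of single-copy
marker loci tagged in the gene models: completeness is the fraction of
expected markers observed, contamination the surplus copy count divided by
the marker-set size. This marker-tag counting replaces an HMM-based marker
search deliberately — the downstream logic needs only the two scalars, and
tags make the ground truth exact. Tiers use the standard MAG thresholds,
inclusive at the boundary (the ≥/≤ reading): HQ at completeness ≥ 0.90 and
contamination ≤ 0.05, MQ at ≥ 0.50 and ≤ 0.10, otherwise FAIL.

## Species dereplication

Pairwise ANI is fragment-based: the smaller genome is cut into 1 kb
fragments (the final fragment of each contig absorbs the remainder, so
every base is covered), each fragment aligned glocally against the other
genome; fragments mapping at ≥ 0.8 identity and ≥ 0.9 coverage enter a
length-weighted identity mean. Alignment fraction (AF) is the mapped
fraction of the smaller genome (the dRep convention; the choice of
denominator is not forced by the species definition and is configurable in
principle). Species clusters are greedy at ANI ≥ 0.95 and AF ≥ 0.30: bins
are ranked by quality, the best unassigned bin seeds a cluster and absorbs
every unassigned bin passing both thresholds against it. A single-stage
greedy pass replaces two-stage sketch-then-ANI schemes — at desk scale the
pre-cluster is purely an optimisation. The representative is chosen
lexicographically by (minimal contamination, maximal completeness, maximal
genome length, smallest id); contamination deliberately outranks
completeness.

## Abundance and read classification

Within a sample, contig relative abundance is depth divided by the summed
depth over all contigs (scale-invariant); species abundance is the median
over the species' contigs, robust to dropped and contaminating contigs.
Medians are reported as-is, with renormalisation to unit sum available by
flag. The classification-rate statistic replaces read mapping with k-mer
containment: a read is classified when ≥ 60% of its 31-mers occur in the
(double-stranded) representative index; the rate is the classified
read-count fraction (read-count, not base, fraction). Exact 31-mer
matching is brutally sensitive to strain divergence (a 31-mer survives 1%
divergence with probability ≈ 0.73), so rates against a strain-divergent
catalog sit well below 1 even when every read originates from a cataloged
species — a property of the statistic, not a bug.

## Protein families and KEGG modules

Nonredundant protein families use greedy incremental clustering in
descending length order with membership at ≥ 0.5 identity over ≥ 0.9 of
the shorter sequence. Assignment of query proteins to families takes the
best-scoring representative with ≥ 30% query coverage and raw score ≥ 80.
The raw-score threshold is the stand-in for a BLAST E-value cutoff
(Karlin–Altschul statistics are out of scope): on a simulated null of
3000 unrelated random 300-aa pairs the maximum local score observed was
78, only ~2% of pairs even shared a 5-mer seed, and no pair passed the
combined coverage+score predicate; a smaller null regression lives in the
test suite.

KEGG module definitions are parsed with a recursive-descent grammar:
space-separated top-level steps (all required), commas for alternatives,
`+` for complex subunits (all required), parentheses for grouping, and
`-`-prefixed optional components (ignored). Completeness is the fraction
of satisfied top-level steps — per-step rather than per-KO granularity, so
a module with one missing alternative step scores the same regardless of
how many KOs that step lists.

## SNV calling and selection pressure

Variants are called from per-site base counts under a binomial error null:
per-base error rate 0.001 split evenly over the three non-reference bases,
upper-tail probability of the observed count, Benjamini–Hochberg across
all tested site/alternative pairs. A record is emitted only if depth ≥ 5,
alternative frequency ≥ 0.05 and q ≤ 1e-6, keeping the most frequent
passing alternative. Classification substitutes the alternative into its
containing codon (strand-resolved) and translates both codons.

The selection statistic is a Ka/Ks (pN/pS) ratio with Nei–Gojobori site
normalisation: per coding position, the fraction of the three possible
substitutions that are synonymous accrues to the synonymous site total.
Normalisation matters — raw nonsynonymous/synonymous count ratios sit near
3 under neutral accumulation because codon structure offers ~3× more
nonsynonymous opportunities, which would make "positive/negative
selection" statements ill-defined. Both ratios are emitted; the
site-normalised one is the headline (neutral → 1, purifying < 1). Depth
correction divides each sample's class counts by the species' mean
sequencing depth in that sample before forming ratios. Per species ×
environment, the default is the mean of per-sample ka′/ks′ ratios
(samples with ks′ = 0 are excluded and counted); a pooled variant forms
one ratio from summed depth-corrected counts and is selectable by flag,
since the averaging order is a genuinely open choice. Per-COG ratios use
the pooled form — per-COG per-sample synonymous counts are often zero —
and categories with fewer than 10 SNVs are reported undefined rather than
infinite.

## HGT detection

Candidates come from a best-match screen over gene nucleotide sequences: a
gene is flagged when its best cross-taxon-group hit (≥ 0.9 identity over
≥ 50% of the gene) is stronger than its best within-group hit in another
genome. The 50% coverage floor is essential: chance seed k-mers between
unrelated genes otherwise yield short perfect local alignments that read
as identity-1.0 hits. Symmetric detections of one gene pair merge into one
event. Orientation uses group support — the side whose group-mates also
carry close homologs is the donor (vertical inheritance leaves homologs
among relatives); equal support is reported as ambiguous rather than
guessed.

Divergence is 1 − nucleotide identity of the donor/recipient gene
alignment, and events with divergence strictly below 1% are "recent".
Nucleotide rather than protein divergence is the default because the
recency threshold lives on the nucleotide scale: at 0.5% nucleotide
divergence the protein-level divergence of a typical gene is already ≈ 1%
(three sites per codon, roughly 70% of substitutions non-silent), which
would misclassify genuinely recent transfers. The level is configurable.

Phylogenetic screening builds the genome tree by neighbor joining on
1 − ANI distances over all genomes (unalignable pairs at distance 1) and
the gene's tree over homolog carriers from best-homolog protein
distances. An event is validated when, by edge count, the recipient's
gene sits closer to a donor-group carrier than to any carrier of its own
group, and no farther from the donor group than the genome tree predicts:
a transferred gene nests inside the donor clade, a vertical family keeps
the recipient with its own relatives. With fewer than four carriers the
comparison is degenerate and the event passes as "unvalidated". COG
contrast between recent and non-recent events uses per-category 2×2
Fisher exact tests with BH correction.

## BGC networks

Two clusters share a gene when a protein of one aligns to a protein of the
other covering ≥ 50% of the query with identity strictly > 50% (each query
pairs with at most its best hit). Query coverage is directional, so the
unordered pair counts as shared if the criterion holds in either direction
— the permissive reading of a query-anchored definition. Edges require at
least one shared gene and carry the mean identity of shared pairs;
connected components (including singletons) are the subnetworks, and the
summary table lists each component's size, product classes and taxa
spanned. Nodes are individual BGCs, not per-species merges.

## Synthetic data: what it emulates and what it does not

The generator produces species as independent random genomes (between-
species ANI ≈ 0) carrying 300–1500 nt ATG-initiated, stop-terminated genes
on both strands with 50–500 nt spacers (~80–90% coding density), plus 100
designated 300 nt marker genes, one per dedicated short contig, so that
bin completeness/contamination can be realised *exactly* by dropping or
adding whole marker contigs. Derived genomes at controlled ANI are made by
uniform random substitution; within-species bins are drawn at 0.985–0.998
identity from their reference so that pairwise bin-to-bin ANI stays at or
above ≈ 0.97 — two bins independently mutated to 0.97 from the reference
would sit near 0.94 pairwise, below the species threshold. Coverage noise
is lognormal with mean 1 (the standard overdispersion model); pileups
plant SNVs with verified class composition, or under an explicit selection
model (synonymous proposals always accepted, nonsynonymous with a given
acceptance probability, so acceptance 1 is neutral and the planted
acceptance is the expected site-normalised Ka/Ks). Transfers copy a donor
gene, substitute the requested divergence fraction, and append it behind a
spacer to a recipient contig; BGC families share a mutated hallmark
protein.

What this does not emulate: read-level errors and mapping (coverage and
pileups are generated directly), assembly chimerism, within-species
recombination or linkage, conserved-core homology between species (all
species are unrelated), real marker-gene detection, and real database
annotation (KO/COG/BGC labels are inputs by construction). Passing tests
therefore demonstrate that each procedure recovers what was planted under
its own stated model — not that the procedures are robust to artifacts
these simplifications remove.

## Pipeline and problem sizes

`skincat run` executes simulate → qc → derep → abundance → function → snv
→ hgt → bgcnet on one synthetic scenario, writing TSV/FASTA/JSON outputs
and a manifest of parameters plus SHA-256 checksums; reruns with the same
config and seed are byte-identical (sorted outputs, fixed float
formatting, one seed feeding every random stream). All thresholds default
to the catalog-procedure values (0.90/0.05, 0.50/0.10, 0.95/0.30, 5, 0.05,
1e-6, 0.01, 0.5/0.9, 0.3, 0.5/0.5). The bundled scenario uses 4 species in
2 phylum-like groups, 30 kb genomes with 20 genes and 20 markers, 2 bins
per species, 6 samples over three skin environments with per-environment
nonsynonymous acceptance 0.9/0.6/0.3 (sebaceous/moist/dry), 2 planted
transfers and 2 BGC families — sizes chosen so a full run takes seconds
while every stage still has planted signal to recover. In this end-to-end
setting HGT divergence is measured between strain-level representatives,
so it includes strain drift on top of the planted transfer divergence;
recency there reflects the total divergence, while the dedicated HGT
scenario (pristine references plus siblings) round-trips the planted
recency exactly.

## Known limitations

- The greedy single-pass clustering (species and protein families) is
  order-dependent by design (quality rank / length rank); it matches the
  stated procedures but is not a global optimum.
- The aligner's banded extension can underestimate identity for pairs with
  large indels relative to the band; the synthetic data is
  substitution-only, matching the thresholds' intent.
- NJ-based HGT validation uses edge counts, which are coarse for very
  small carrier sets; events are then conservatively "unvalidated".
- The binomial error model treats sites independently; no local
  realignment or mapping-quality modelling exists, matching the pileup
  abstraction.
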