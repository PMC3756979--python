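# Methods

This note documents the models behind each stage of the pipeline, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices that were genuinely open.

## Identification of lineage-specific duplicates

**Homology search.** External aligners are replaced by an internal
desk-scale search: affine-gap dynamic programming (BLOSUM62, gap open
−11, extend −1, Biopython's `PairwiseAligner`) over candidate pairs
pre-filtered by shared 5-mers, with Karlin–Altschul e-values
(λ = 0.267, K = 0.041) attached to raw scores. Reported identity,
coverage and intervals come from the maximal homologous run of aligned
columns (best-scoring segment under match +1 / mismatch −1): affine
local alignments occasionally chain through low-identity non-homologous
stretches at marginally positive score, which would otherwise inflate
coverage — most visibly on chimeric genes, whose donors must appear as
near-disjoint query regions. The raw DP score (hence the e-value) is
unchanged by the trimming. Coverage uses the longer protein as the
denominator (conservative; the convention is not fixed by common usage)
and identity is per aligned column.

**Orthologs and synteny.** Orthologs are reciprocal best hits with both
e-values < 0.001; ties on (score, e-value) yield no call. Synteny blocks
are maximal collinear chains of RBH gene anchors (longest-increasing-
subsequence DP, both orientations, at most `max_gap = 5` skipped genes
between consecutive anchors, greedy chain extraction, each gene in at
most one block per genome pair). The nucleotide chain/net machinery is
deliberately replaced by gene-anchor chaining: every downstream
criterion is stated at gene level, so anchor chains give the same
per-gene calls without external binaries. The "aligned footprint" of a
block — used for the synteny-membership and polarization fractions — is
the union of its anchor gene bodies; a gene inserted between anchors
overlaps nothing.

**Lineage-specific calls.** A focal gene is lineage-specific iff its
footprint overlap fraction is < 0.3 against **all** outgroups *and* it
has no RBH ortholog in **any** outgroup. Both copies of a very recent
duplicate can tie for reciprocity (44/137 of the motivating cohort had
no substitutions at all); in that case neither copy gets an RBH call and
both may be lineage-specific, mirroring the "two paralogs sharing one
best hit" situation. Pairing then attaches each lineage-specific gene to
its best-scoring partner with identity ≥ 50 % and coverage ≥ 70 %.

**Classification.** Tandem is checked first (adjacent gene-order
indices, same contig). Segmental requires a companion paralog pair with
≤ 10 intervening genes (endpoints excluded) on both segments and the
same relative order — the gene-level reading of "the two segments are
mutually syntenic". Everything else is dispersed.

**Polarization.** The copy with < 30 % of its length in syntenic
footprints is the daughter (NDG) when exactly one copy qualifies. On a
tie the gene tree decides: all sequences are star-aligned onto copy 1
through global protein alignments, nucleotide p-distances feed
neighbor joining (Biopython's constructor), and the copy with the
smaller patristic distance to its nearest outgroup ortholog is the
parent — accepted when ≥ 50 % of 1000 codon-column bootstrap resamples
agree, else `undetermined`. Because a post-speciation duplication makes
the two copies sisters in the true topology, "clusters with the
orthologs" is operationalized as this distance comparison; it is
antisymmetric in the input order by construction. Outgroup sequences
for the tree are the best (not necessarily reciprocal) hits, so the
protein-identical tie case can still be polarized through synonymous
divergence.

**Chimeras.** A gene is chimeric when ≥ 2 donors hit query regions whose
reciprocal overlap is < 20 % of either interval (threshold configurable;
not fixed by any convention). A donor whose hit interval overlaps a
transposable-element annotation marks the fusion as TE-derived.

## Codon models

The substitution model is GY94-style over the 61 sense codons: rate
κ-scaled for transitions, ω-scaled for nonsynonymous changes, equal
codon frequencies by default (F3×4 optional), scaled to one expected
substitution per codon per unit branch length. With equal frequencies
the rate matrix is symmetric, so transition matrices come from one
`eigh` per (κ, ω) — exact for any t and fast enough for hundreds of ML
fits. Pairwise fits maximize (t, κ, ω) by L-BFGS-B over log-parameters
(bounds t ∈ [1e-6, 50], κ ∈ [0.1, 20], ω ∈ [1e-4, 99]; ftol 1e-12),
starting from Nei–Gojobori estimates plus one fixed fallback start.
Fixed-ω models (0.5 and 1) re-optimize (t, κ); LRT p-values use χ²₁ of
2ΔlogL. Ka and Ks are decomposed from the ML fit (rate flux × site
proportions under the same model at ω = 1); NG86 with pathway averaging
and Jukes–Cantor correction is kept as an independent cross-check and
is saturation-flagged at corrected proportions ≥ 0.75.

Pairs with zero substitutions are reported as their own category
(Ka = Ks = 0, no LRT — the test is undefined for them). The branch model
is Felsenstein pruning over site patterns with two ω classes (one tagged
foreground branch, `#1` in the newick string); the LRT fixes the
foreground ω at 1. χ²₁ calibration of the pairwise LRT is checked at
500 codons, where the acceptance suite finds the empirical size within
[0.03, 0.08]; at 300 codons and below the test is visibly conservative
(a finite-sample property of the χ² approximation, not an optimizer
artifact).

## Population genetics

π is the mean pairwise difference per site and θ_W = S/(a₁L), per
partition (all sites over the full gene span; synonymous and
nonsynonymous over NG86-style fractional site totals of the CDS, each
SNP classified by substituting its alternate allele alone into the
reference codon; premature stops count as nonsynonymous and are
logged). Tajima's D uses the 1989 constants. Fu & Li's statistics
default to the starred, outgroup-free variants (sample singletons;
Fu & Li 1993 with the later corrected variance forms), because no
polarization procedure is assumed; the unstarred versions activate when
an ancestral-allele map covers ≥ 90 % of SNPs.

Significance is empirical: candidate null loci are sorted by
coordinate, thinned greedily left-to-right to ≥ 25 kb spacing per
chromosome (deterministic and input-order independent), subsampled with
a seed to ~800 loci, and the observed statistic is compared by
inclusive one-tail proportion — lower tail when negative, upper tail
when positive, raw proportions reported even when 0 (an add-one
smoothing flag exists, default off). Note the signed fold means the
p-value of a null locus is uniform only within each tail (the fold
point, 0, is not exactly the null median); the calibration tests check
the one-tail probability integral transform and the doubled small-p
rate this construction implies. Per statistic, p-values of all daughter
and parent genes are pooled and BH-corrected; a gene is called under
selection when any statistic has q < 0.05 *and* a negative observed
value. Storey's q-value was considered and not used — BH is the
assumption-light default.

The MK test counts, per coding site of the focal gene: fixed differences
(sample monomorphic, differing from the codon-aligned paralog) and
polymorphisms (segregating sites), each classified syn/nonsyn against
the focal reference codon; fixed-difference sites are excluded from the
polymorphism cells by construction. Fisher's exact test (two-sided) on
the 2×2; p is missing when the table is empty.

## Expression

EST enrichment uses the 2×2 exactly as classically constructed — gene's
ESTs in the tissue vs its other ESTs, against the tissue's total vs all
other ESTs over **all** genes (the gene of interest is not subtracted
from the pool rows) — with one-sided Fisher tests BH-corrected across
every gene × tissue combination. EST-to-gene assignment requires
identity ≥ 95 %, e ≤ 1e-20, score ≥ 100 and a ≥ 5-point margin over the
second-best gene. Tiling specificity is a per-gene Z-score across
tissues (Z > 2.5; zero-SD profiles get no call). The RNA-seq expressed
threshold (FPKM ≥ 1.0, inclusive) is a documented sensitivity knob, not
a derived constant. Divergence categories compare enriched-tissue sets
(same / gained / lost / switched) and are symmetric-consistent under
argument swap; cross-platform comparisons require an explicit flag.
Cis-element sets compare as strict-subset relations; two empty sets mean
no annotation, not "same".

## Methylation

The non-conversion error rate is total methylated reads over total reads
on a control contig with no methylation activity (the chloroplast
analogue); a warning fires below 1000 covered control cytosines. Each
covered cytosine gets a one-sided binomial p (P(X ≥ k | n, error rate)),
and calls are BH-corrected at q < 0.05 genome-wide — the correction step
is this package's choice; uncorrected per-cytosine calls would be badly
anti-conservative at genome scale. Contexts (CG/CHG/CHH, H = A/C/T) are
read strand-aware from the genome, on the reverse complement for minus-
strand cytosines. Gene-body conservation counts aligned cytosine
positions called in both copies and tests the conserved fraction
(conserved methylation **and** conserved un-methylation) against the
background conservation of all duplicate pairs; the default is the
lower tail (significantly *low* conservation), with the direction
configurable — the motivating analysis described an upper-tail test but
reported low-conservation pairs, an inconsistency resolved here in
favor of the reported result. Promoter and terminator levels use
strand-aware 200 bp windows (truncated at contig edges, logged),
upper-tail binomial against the genome-wide background level, counting
called cytosine bases rather than reads.

## Synthetic data: what it does and does not emulate

All generators take explicit seeds and are byte-deterministic; none
keeps global state.

* **Genomes** — one chromosome per species, genes laid out with 200 bp
  random spacers, backbone order conserved across species with small
  adjacent-swap noise in outgroups, sequences diverged independently
  from common ancestors under the codon model (default branch length
  0.15 per species, ω 0.2, κ 2 — recent, constraint-dominated
  divergence). Daughters of planted duplicates add 0.05 of extra branch
  length, making them recent relative to speciation, as in the
  motivating system. Three tandem, one two-gene segmental block, three
  dispersed duplicates and one mid-gene chimeric fusion are planted by
  default; tandem parents and non-tandem insertion slots keep ≥ 13
  backbone genes of separation so the classification rules are
  unambiguous by construction. Not emulated: strand variation, introns,
  gene loss, transposable elements, real intergenic structure.
* **Haplotypes** — Hudson's discrete-lineage coalescent with
  infinite-sites mutations (θ per locus on the Watterson scale,
  E[S] = a₁θ), chosen precisely because closed-form expectations give
  free acceptance tests. The rare-variant excess of a sweep is mimicked
  by reassigning a stated fraction of mutations to external branches —
  a documented caricature sufficient to give the neutrality tests
  signal; no recombination, demography, or linked selection. Defaults
  follow the motivating study's design: 80 haplotypes, and a 2.21 %
  bisulfite error-rate analogue elsewhere.
* **EST counts** — multinomial tissue allocation (default 60 ESTs/gene,
  uniform base probabilities); enriched genes multiply one tissue's
  probability by the enrichment factor (default 10) and renormalize.
* **Bisulfite** — per-cytosine coverage ~ Poisson(depth), methylated
  reads ~ Binomial(n, 0.8) at truly methylated positions and
  Binomial(n, error rate) elsewhere; a chloroplast-like control contig
  with zero true methylation is always present so the error rate is
  estimable from the output alone.
* **Cis elements** — element sets drawn per divergence mode so the mode
  is exactly recoverable by set comparison.

Passing tests on these generators demonstrates the statistical
machinery is correct under its stated model; they say nothing about
alignment artifacts, mapping biases, annotation errors or demographic
confounding in real data.

## Problem sizes and tolerances

The test and acceptance runs use: 100-gene, 4-species genome
simulations (seeds 1–5) for exact recovery; 200 replicates of 500-codon
pairs for ω recovery (mean within 10 % of 0.2) and 500 replicates for
LRT size; 10,000 coalescent replicates for E[S] and E[π] (3 Monte-Carlo
SE); exhaustive 2×2 Fisher-vs-hypergeometric agreement to grand total 24
plus a seeded sample to 200. Likelihood identities (pairwise vs two-leaf
pruning) hold to 1e-8; logL monotonicity of nested models to 1e-6.

## Known limitations

Gene-anchor synteny cannot express partial-gene syntenic coverage, so
the < 30 % / > 30 % polarization fractions are near-binary in practice
(as they are in the motivating data). The desk-scale homology search is
quadratic in gene count and intended for thousands, not tens of
thousands, of genes. The branch model supports small, fixed, fully
resolved trees with one foreground branch. Site models (positive
selection on individual codons), recombination-aware statistics, and
methylation region segmentation are out of scope.
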