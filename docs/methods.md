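# Methods

This note records the modelling assumptions, parameter choices and known
limitations of `radhap`, in the spirit of a methods appendix.

## Haploid leading-haplotype genotyping

A RAD locus is the set of aligned reads of one individual sharing
(chromosome, strand, 5′ reference anchor). The anchor is the post-clipping
alignment start for forward reads and the alignment end for reverse reads;
forward and reverse stacks at one cut site are treated as distinct loci.
This grouping is deterministic and matches single-end RAD stacking; it does
not attempt to merge the two flanks of a cut site.

Within a stack, the call is the unique sequence of highest count. Three
exclusion rules apply, in this order:

1. **Tie** — two or more sequences share the top count. The locus is
   excluded for that individual rather than broken arbitrarily; for a
   balanced heterozygote with depth *d* this happens with probability
   C(d, d/2)·2^(−d) for even *d*, a prediction the test suite checks
   exactly.
2. **Copy number** — a unique leader below `min_copies` (2 default,
   5 stringent) is insufficient support.
3. **Excess depth** — stacks whose *total* depth (all sequences, not just
   the leader; collapsed repeats inflate the total) strictly exceeds
   `depth_factor` (4.5) times the individual's expected depth are flagged
   as repeats. Expected depth = total reads / total stacked loci, computed
   per individual over *all* stacks before any exclusion. Per-individual
   normalization makes the cutoff robust to library-size differences; a
   pooled-across-individuals variant would shift the cutoff for uneven
   libraries but is not implemented. Depth exactly at the cutoff is
   retained ("beyond" read strictly).

Reads containing N pass QC if they match the residual; an N participates
in haplotype identity literally, but any alignment column containing N is
excluded from SNP detection, so no ambiguity code ever reaches the
supermatrix.

## SNP acceptance and the spacing rule

Within each shared locus, a column is polymorphic when ≥2 distinct
non-N nucleotides occur. The indel guard accepts the first polymorphic
offset and each later offset only if it lies at least `min_spacing`
(8 default, 12 stringent) from its **immediately preceding polymorphic
offset, accepted or not** — a rejected position still evidences an indel
cluster. The alternative reading (distance from the previous *accepted*
SNP) admits weakly more sites; both interpretations are monotone in
`min_spacing`, and the implemented one is the more conservative. Offsets
are 0-based within the 70-bp locus in read orientation; the sites TSV
records (chrom, anchor, strand, offset) so coordinates stay interpretable
for reverse-strand loci.

## Likelihood model and tree search

The engine implements GTR-family reversible models. Q is normalized so the
rate mixture has mean 1; under +I the gamma-category rates are inflated by
1/(1−p_inv), keeping branch lengths in expected substitutions per site
across all classes. Rate heterogeneity uses 4 equal-probability discrete
gamma categories represented by their exact category means (computed from
incomplete gamma functions, renormalized to mean 1). Base frequencies are
empirical counts, not ML-optimized.

Likelihoods come from Felsenstein pruning over pattern-compressed columns;
no numerical rescaling is applied, which is safe for the tens-of-taxa,
short-branch regime this package targets (partial likelihoods stay far
above double-precision underflow below roughly 200 taxa at these
divergences). Branch-length optimization is coordinate-wise bounded Brent
on [1e−9, 10] substitutions/site with tolerance 1e−6, using cached
below-edge and above-edge conditionals so each one-dimensional evaluation
is a single 4×4 mixing step per rate class.

The topology search is NNI-only hill climbing from a neighbor-joining
start on p-distances (negative NJ lengths clamped to 0): each candidate
interchange is scored after re-optimizing the focal edge, accepted
improvements are kept, and a full branch-length pass closes each sweep;
the search stops when a sweep gains < 1e−4 log units. NNI suffices at
these data sizes (≤ ~70 taxa, strong SNP signal); SPR is deliberately out
of scope. The returned tree can never score below its NJ start, a property
the tests assert.

Model selection fits each of JC/HKY/GTR × {+Γ} × {+I} on a fixed NJ
topology (Nelder–Mead on log/logit-transformed free parameters, alternated
with branch-length passes) and minimizes AIC = 2k − 2lnL with k = free
model parameters + branch lengths; ties break toward fewer parameters.

Bootstrap replicates resample alignment columns with replacement at full
length and re-run the search with model parameters **fixed** at the
full-data estimates (re-estimation per replicate would multiply cost for
little change at these signal strengths). A single seed drives NNI sweep
order and the per-replicate resampling through independent derived
streams, making supports bit-for-bit reproducible.

No ascertainment-bias correction is applied to the SNP-only alignment
(none is applied in the protocol this package implements). Branch lengths
are therefore inflated relative to whole-locus data; topology and support
are the intended outputs.

## Ordination

Genetic distance is the uncorrected p-distance on SNP columns (a
JC-corrected variant is available); PCoA is classical scaling with
negative eigenvalues retained and reported, no Cailliez/Lingoes
correction, and a deterministic sign convention (first nonzero loading of
each axis positive). Outgroup individuals are excluded by default,
mirroring the analysis protocol.

## Synthetic data generator

The simulator emulates the statistical structure the pipeline assumes:
Yule trees (the generator stops at the last speciation, so every pending
lineage is extended by one additional exponential waiting time — without
this, the final two taxa would be identical); 70-bp loci whose residual
prefix is exempt from mutation and sequencing error so QC pass rates are
controlled by design; per-site discrete-gamma rates matching the chosen
model; optional heterozygotes carrying a second allele one substitution
away; negative-binomial read depth (mean 20, dispersion 5 by default —
realistic RAD overdispersion) with repeat-like loci at doubled mean; and
independent per-base miscalls at 0.2%. Reads are emitted pre-aligned
(SAM written from truth coordinates) because read alignment is an external
step; a FASTQ-only mode exists for users who want to exercise their own
aligner.

What the simulator does **not** emulate: PCR duplicates, quality-score
structure, allele dropout from restriction-site polymorphism, indels, and
reference bias. Passing the recovery tests therefore demonstrates the
pipeline's correctness under its own model, not robustness to every
artefact of real libraries.

Default generator settings (12 taxa, 800 loci, 20× depth, 0.2% error,
1% heterozygosity) define the standard validation condition; under it the
full pipeline recovers the true 12-taxon topology exactly in ≥9 of 10
seeds. Where recovery fails, the inferred tree ties the truth's likelihood
(short internal branches carry no signal at this alignment length) — the
failure is statistical, not algorithmic, and the test suite distinguishes
the two.

## Problem sizes and validation choices

Validation runs use 12 taxa × 800 loci for topology recovery (with the
generating model family, GTR+G, supplied rather than re-selected — model
selection is exercised separately on data with a known generating model),
6 taxa × 150–300 loci for pipeline round-trip and determinism checks, and
10,000 loci for the heterozygote tie-rate comparison. Bootstrap counts in
tests are 10–200; the production default remains 500.

## Degenerate inputs and tie-breaks

Empty locus intersections, empty alignments, non-monophyletic outgroups,
<3 taxa for tree building, and exclusions leaving <2 individuals all raise
explicit errors naming the offending entity. Representative selection
(2 deepest-sequenced individuals per population, measured as QC-passing
reads) breaks depth ties by individual id. NJ with exactly 3 taxa solves
the three-point equations exactly.
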