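# Methods

## Problem setting

A non-coding small indel (nc-sindel) is a variant whose reference and
alternative alleles differ in length by at least 1 bp and by less than
100 bp. The package scores the probability that such a variant alters
nearby gene expression, separately per tissue, by supervised learning
on indels labeled through cis-eQTL association statistics. Everything
operates on summary-level inputs: variant coordinates and alleles, the
associated gene, the distance to its transcription start site (TSS),
the FDR-adjusted association q-value and the minor allele frequency
(MAF). No genotype- or read-level data are consumed.

Coordinates are 0-based, half-open throughout; parsers for 1-based
inputs (VCF/ClinVar-style position columns) convert at the boundary via
an explicit flag, since public eQTL releases do not always state their
convention.

## Labeling

Positives: q < 0.05 (minimum over a variant's gene associations, so a
multi-gene variant counts once), |TSS distance| < 100 kb, indel length
|len(ref) − len(alt)| < 100. All comparisons are strict, taking the
thresholds literally; boundary records are excluded. Negative
candidates additionally must share at least one gene with the positive
pool, have q > 0.2 (again the per-variant minimum — a variant with any
sub-threshold association is not a confident null), and must not
overlap any positive's reference span. Span overlap rather than exact
key identity is used because near-duplicate indels at the same locus
would otherwise leak across classes.

The final negative set is balanced and MAF-matched: MAF values are
binned at width 0.05 (configurable) and, per bin, exactly as many
candidates as positives are drawn uniformly without replacement under a
caller seed. If any bin has fewer candidates than positives the
operation fails listing the deficient bins, so the caller can relax the
bin width deliberately rather than receive a silently skewed set. The
same binned-matching machinery drives GC matching of negative regions.

A clinical labeling path mirrors a curated variant-summary table:
positives/negatives are records with clinical significance exactly
"Pathogenic"/"Benign", restricted to the indel variant types
(Insertion, Deletion, Indel, Duplication), length < 100 bp and a
high-confidence review status ("multiple submitters, no conflicts" or
"reviewed by expert panel"). No balancing is applied there.

## Features

*Generic annotations.* A numeric variant × annotation matrix with
missing values. Columns with a missing fraction ≥ 10% are removed
(strictly below keeps), the remainder median-imputed per column.

*Profile features.* For each variant, a reference window of L = 1000 bp
with the variant's first reference base at index L/2. The window anchor
is a design choice: centering is the symmetric option and keeps both
flanks equally informative. The alternative window applies the allele
edit at the anchor, keeps the upstream half byte-identical, and
restores length L by truncation (insertions) or by pulling in
downstream reference (deletions). A multi-track predictor maps each
window to per-track scores in [0, 1]; scores are used as continuous
probabilities, not binarized, since thresholding would discard ranking
signal. One-hot encoding uses channel order (A, G, C, T); N encodes as
an all-zero row rather than an error because real flanks contain N and
the predictor contract must be total.

The bundled predictor is a synthetic k-mer model: track t scores
sigmoid(w_t · c / sqrt(L − k + 1)) with c the window's k-mer count
vector (k = 6 by default, N-containing k-mers skipped) and w_t
standard-normal weights drawn once from a seed. It is deterministic,
total, and sensitive to single-base changes — the contract a trained
deep sequence model exposes — and exists so the pipeline can be
exercised and validated at desk scale; it is not a trained epigenomic
model, and scores from it carry no biological meaning.

The sequence-baseline transform concatenates |ref − alt| with the
relative difference (ref − alt)/(ref + ε), ε = 1e−6; ε only guards
division and is far below the predictor's score resolution.

## Classifier and protocols

XGBoost with logistic objective, histogram tree method, single-threaded
and seeded for bit-reproducibility. Defaults: 200 trees, depth 4,
learning rate 0.1, subsample 0.8, colsample_bytree 0.3. These are sized
for matrices of ~2000 rows × ~1900 columns on one CPU (~10 s per fit);
column subsampling suits the wide, highly correlated profile block.
Deeper/larger ensembles gave no measurable gain on the synthetic
studies while multiplying the runtime.

Pooled k-fold CV stratifies folds by label (guaranteeing both classes
per fold), scores every row exactly once with a model that never saw
it, and computes one AUROC/AUPRC on the concatenated score vector.
AUROC is the standard rank statistic with half-credit ties; AUPRC is
step-integrated average precision. Cross-cohort evaluation removes test
variants whose exact key (chrom:pos:ref:alt) appears in the training
set; span-overlap removal is available as a stricter option.

Baselines: an RBF-kernel soft-margin SVM (C = 1, gamma = "scale",
standardized features, continuous decision-function scores) on the
generic block, and a boosted logistic regression — gradient boosting
with logistic loss on depth-1 stumps — on the profile-difference
features. Kernel and boosting settings are conventional defaults; the
comparisons the package makes are directional, not calibrated to any
external benchmark.

## Enrichment

Peaks are standardized to width-1000 windows around the peak midpoint
(significant at FDR < 0.05); interaction anchors to 2-kb windows around
the anchor midpoint. Interactions are kept if intra-chromosomal with
anchor-midpoint distance ≤ 1 Mb (midpoint distance is the pcHi-C
convention); a tissue/type is analyzed only with more than 100
significant (FDR < 0.1) interactions. Negative regions equal the
positives in count and GC-bin histogram: for interactions they are
drawn from FDR > 0.5 candidates with GC computed on the concatenated
2-kb anchor windows; for peaks they are rejection-sampled genome-wide,
disjoint from the positives and from each other. Windows that would
leave the contig are dropped with a warning.

A variant is "in" a region class when its reference span overlaps any
interval of the class (for interactions, either anchor window — one
anchor hit suffices). A variant overlapping both classes counts in both
cells of its row by default (an exclusive mode, positive wins, is a
flag). OR = (n11·n22)/(n12·n21), +∞ when only the numerator is
positive, undefined when both products vanish. The Fisher test is
one-sided (greater), matching the directional hypothesis that positive
variants concentrate in positive regions; p-values come from the exact
hypergeometric tail (scipy's implementation, log-space internally) and
are verified in the test suite against rational-arithmetic enumeration
for every table with N ≤ 40. Predicted labels use strict score > 0.5 so
the all-tied degenerate case is deterministic.

## Synthetic studies

The generator emulates the statistical shape of the real inputs, not
their biology:

- genome: i.i.d. bases at a target GC of 0.41 (human-like), default
  10 Mb over 2 contigs — large enough to tile disjoint 2-kb region
  slots and keep every variant's 1-kb window in bounds;
- labels: 1000 positives (q ~ U(0, 0.05)) and 4000 negative candidates
  (q ~ U(0.2, 1)); TSS distances U(0, 100 kb); MAF ~ Beta(2, 5)
  truncated to (0, 0.5] for both classes, so MAF matching succeeds by
  construction (a 4:1 candidate ratio keeps every 0.05-wide bin
  covered with overwhelming probability). Decoy records violating the
  TSS bound, duplicate multi-gene rows and out-of-pool genes exercise
  each labeling filter;
- annotations: 45 columns, 10 informative at a +1 SD mean shift for
  positives, three columns with 2% missing entries (kept, imputed) and
  one with 12% (always removed by the filter);
- sequence signal: one k-mer (the "motif", composition constrained to
  the genome's GC so planted repeats cannot confound GC matching)
  receives ±20·profile_effect extra weight on every predictor track. A
  short tandem of the motif is written across each positive variant's
  edit site, so applying the alternative allele destroys the junction
  copy; negative edit sites are scrubbed of the motif. The pad around
  the edit is deliberately short (k − 2): with few embedded copies the
  per-track logistic stays in its responsive range, where losing the
  junction copy moves the score appreciably. Note that because a
  length-changing edit only shifts downstream sequence, k-mer content
  differences between the two windows are inherently local to the
  junction and window tail — which is exactly where the signal is
  planted;
- regions: the genome is tiled with disjoint 2-kb slots; a fraction
  OR/(1+OR) of the positives (OR = 3 by default) is placed in
  "regulatory" slots and the rest in "background" slots, negatives
  split 50/50. Memberships are realized by exact counts (shuffled)
  rather than independent coin flips, so the planted odds carry no
  binomial noise on top of the unavoidable subsampling noise of the
  downstream matching steps.
  Regulatory slots become anchors of significant PE interactions
  (partner anchors in variant-free slots within 1 Mb), background slots
  anchors of FDR > 0.5 candidates; because the pipeline's GC-matched
  subsampling of candidates is independent of variant placement, it
  rescales the negative-region column of the contingency table without
  biasing the odds ratio. Decoy inter-chromosomal and over-distance
  interactions, a PP interaction set and significant/non-significant
  peaks exercise the remaining filters.

What the generator does **not** emulate: linkage disequilibrium,
mutation-rate heterogeneity, realistic annotation correlation
structure, sequence-context-dependent eQTL effects, or any trained
epigenomic model. Passing tests therefore demonstrate that the
machinery is correct and recovers planted signal at the stated effect
sizes — not that the scores would reach any particular accuracy on real
cohorts.

## Problem sizes and determinism

The default validation study uses 1000+1000 variants, 919 predictor
tracks, 5 folds, 500 planted regulatory regions against 750 background
candidates; the full pipeline (signal study, generic-only ablation,
null study, enrichment) completes in a few minutes on a single CPU.
All randomness flows from explicit integer seeds through
`numpy.random.Generator`; spawned substreams separate the genome,
study, annotation and region draws, so components are individually
reproducible. Re-running any stage with the same seed reproduces its
outputs byte-for-byte.

## Known limitations

- The synthetic predictor's k-mer counts are position-independent, so
  ref/alt differences are junction-local; a trained sequence model
  would respond to positional context as well.
- Interaction-set construction assumes anchors fit their contig after
  2-kb standardization; anchors at contig edges are dropped, not
  clipped.
- The per-variant minimum-q rule for negative candidates is stricter
  than filtering record-wise; cohorts where the same variant has many
  weak associations lose a few candidates.
- No multiple-testing correction is applied across enrichment tests;
  reported p-values are raw.
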