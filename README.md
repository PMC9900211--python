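# regindel

Tissue-specific supervised scoring of **non-coding regulatory small
indels** (nc-sindels): insertions/deletions shorter than 100 bp whose
ref and alt alleles differ in length and which may alter nearby gene
expression.

Current sequencing studies often lack the power to pinpoint such
variants directly (low minor allele frequencies, small effect sizes).
`regindel` takes the supervised route: it learns from indels already
labeled by cis-eQTL analysis and predicts a regulatory potential score
for any other indel, per tissue.

## What the package does

1. **Labeling** (`variant_sets`). Positives are eQTL indels with
   q < 0.05, |TSS distance| < 100 kb and length < 100 bp; negative
   candidates have q > 0.2, share a gene with the positive pool and do
   not overlap any positive on the reference. Negatives are sampled to
   a balanced set whose minor-allele-frequency histogram equals the
   positives' exactly (fixed-width bins, uniform within-bin draws).
2. **Featurization** (`features`). Each variant gets
   *generic annotations* (variant × annotation matrix, columns with
   ≥ 10% missing values dropped, the rest median-imputed) plus
   *epigenomic profiles*: a 1000-bp reference window centered on the
   variant and an equal-length alternative-allele window (allele edit
   applied at the center, tail re-padded from downstream reference) are
   each mapped by a multi-track sequence model to per-track scores in
   [0, 1]. With the 919-track reference configuration the profile block
   is 919 + 919 = 1838 columns.
3. **Model and evaluation** (`model_eval`). An XGBoost classifier per
   tissue; pooled 5-fold cross-validation (held-out fold scores are
   concatenated before a single AUROC/AUPRC is computed), cross-tissue
   and independent-study transfer with exact variant-key overlap
   removal, a feature-set ablation (generic / +ref / +ref+alt), and two
   re-implemented baselines (RBF-SVM on generic annotations; boosted
   logistic regression on |ref−alt| and relative profile differences).
4. **Enrichment** (`enrichment`). Peaks standardized to 1-kb windows
   (FDR < 0.05 positives) and promoter-centered chromatin interactions
   (intra-chromosomal, ≤ 1 Mb, 2-kb anchor windows, FDR < 0.1
   positives, > 100 required per tissue) with GC-matched negative
   regions; the 2×2 table n11..n22 of variant label × region class
   gives the odds ratio OR = (n11·n22)/(n12·n21) and a one-sided
   Fisher's exact p-value, computed for true labels and for predictions
   thresholded at score > 0.5.
5. **Synthetic studies** (`synthetic_data`). A generator that emits
   every input above (genome FASTA, eQTL tables, annotations, peaks,
   interactions) with planted, controllable signal — informative
   annotation columns, a motif-disruption sequence signal tied to the
   bundled k-mer predictor, and region memberships realizing a target
   odds ratio — so the full pipeline runs and is validated without any
   external download.

The trained deep sequence model itself (DanQ/DeepSEA-style network) is
out of scope; the profile predictor is a pluggable interface, and the
bundled implementation is a deterministic synthetic k-mer model.

## Worked example

```bash
regindel simulate --seed 7 --n-pos 200 --n-tracks 32 --out demo/
regindel build-trainset --pos-eqtl demo/eqtl_positive_source.tsv \
    --neg-eqtl demo/eqtl_negative_source.tsv --tissue lung --seed 7 \
    --out demo/lung
regindel featurize --genome demo/genome.fa --trainset demo/lung.trainset.tsv \
    --annots demo/annotations.tsv --n-tracks 32 --seed 7 \
    --out demo/features.tsv
regindel eval --mode cv --train demo/features.tsv --folds 5 --seed 7 \
    --report demo/cv.tsv
cat demo/cv.tsv
```

Output of the last command:

```
protocol	train	test	auroc	auprc	n_test
cv_pooled	tissue	tissue	0.9784249999999999	0.9790501972467752	400
```

The 200 planted positives and their 200 MAF-matched negatives are each
scored once by a model that never saw them; the pooled AUROC of ~0.98
reflects the planted annotation signal at these settings (the
`featurize` subcommand instantiates a generic synthetic predictor, so
profile columns are present but uninformative here — plugging in the
study's own predictor, as the library API and `scripts/acceptance.py`
do, adds the sequence signal). `regindel train`, `predict` and `enrich` continue the chain:
`predict` writes a `(variant_key, tissue, score)` table, and `enrich`
reports n11..n22, OR and p per region class for true and predicted
labels.

The same steps are available as library calls
(`simulate_study`, `build_labeled_set`, `featurize_labeled_set`,
`cv_pooled`, `enrich_report`) — see `docs/methods.md` for the model
details and parameter rationale.

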