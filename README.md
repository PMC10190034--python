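# splicetree

Consensus splice-impact prediction for small genetic variants.

A variant anywhere in a gene can disrupt splicing — by damaging a donor
(5′SS) or acceptor (3′SS) splice site, creating a cryptic site, weakening an
exonic splicing enhancer (ESE) bound by SR proteins, or strengthening a
silencer (ESS) bound by hnRNP A1. Individual in-silico predictors are
specialised: deep-learning tools excel at canonical sites, precomputed
databases are blind outside their search space, and nobody handles ESE/ESS
variants well. `splicetree` is for variant analysts and method developers
who want a single calibrated 0–1 splice-altering score per variant that
draws on many predictors at once and degrades gracefully when some of them
do not score a variant at all.

## What it does

1. **Filter** a VCF to variants in protein-coding genes with population
   allele frequency ≤ 0.01 (missing frequency passes: absence implies
   rarity).
2. **Annotate** each variant with rule-based splice features: region class
   (donor = last 3 exonic + first 6 intronic nt; acceptor = first 3 exonic
   + last 12 intronic nt), distances to the nearest splice sites, ESE/ESS
   position-weight-matrix score deltas, AG/GT dinucleotide
   creation/removal, AG-exclusion-zone (AGEZ) membership with the 15-nt
   branchpoint margin separating cryptic-acceptor use from exon skipping,
   U12 (minor spliceosome) intron membership, and intronic deletions that
   shrink an intron below the ~45 nt minimum.
3. **Ingest** external predictor scores (SpliceAI-, MMSplice-, Spliceogen-,
   CADD-, SPIDEX-, dbscSNV-, branchpoint-predictor-style tables). Complex
   variants (MNV/insdel) are decomposed into a deletion + insertion and
   each score category takes the maximum over the scored parts.
4. **Score** with a C4.5/C5.0-style decision tree that handles missing
   features natively via fractional instance weighting — no imputation.
   Splits maximise the information-gain ratio computed on rows where the
   feature is observed; rows missing the split feature travel down both
   branches weighted by the observed branch mass, and prediction mirrors
   this with a mass-weighted mixture. Leaves emit Laplace-smoothed
   probabilities (pos+1)/(n+2), so the output is a continuous score
   s ∈ [0, 1]. When both the SpliceAI-style and MMSplice-style score
   groups are entirely missing, the final score is forced to 0 (those
   tools' hard-coded region filters otherwise inflate false positives).
5. **Calibrate** thresholds on labelled variants from the precision-recall
   sweep: the F1-optimal point (default calling threshold 0.61), a
   high-specificity point (default 0.83), and per-tool thresholds at a
   target precision (0.95) for fair cross-tool, region-stratified
   comparison.

A synthetic-fixture generator builds a complete toy universe (genome with
canonical GT..AG introns, planted branchpoints and ESE motifs, variants in
every region class, class-conditional tool scores with region-dependent
missingness) and labels variants through a latent ΔPSI thresholded at 10%
— so the entire pipeline is testable offline.

## Worked example

```bash
splicetree simulate --seed 7 --n-genes 8 --out-dir sim
splicetree annotate --vcf sim/variants.vcf --gtf sim/models.gtf \
    --fasta sim/genome.fa --scores-dir sim \
    --branchpoints sim/branchpoints.tsv --u12 sim/u12.bed --out-prefix ann
splicetree train --features ann.features.tsv --truth sim/truth.tsv \
    --folds 5 --seed 1 --out-prefix fit
splicetree score --vcf sim/variants.vcf --gtf sim/models.gtf \
    --fasta sim/genome.fa --scores-dir sim \
    --branchpoints sim/branchpoints.tsv --u12 sim/u12.bed \
    --model fit.model.json --out-prefix scored
splicetree evaluate --scored scored.tsv --truth sim/truth.tsv --out-prefix eval
```

which logs:

```
INFO splicetree: variants: 200 input, 200 in regions, 200 after AF filter
INFO splicetree: mean auROC 0.9683, mean auPRC 0.9692
INFO splicetree: 121/200 variants called splice-altering at >= 0.61
INFO splicetree: auPRC 0.9461; F1-optimal threshold 0.602
```

Reading the output: 200 simulated variants pass both filters; 5-fold
cross-validation of the consensus tree reaches mean auROC 0.97 / auPRC
0.97 on this small fixture; at the default calling threshold 0.61, 121
variants are called splice-altering; and on the truth labels the scored
set yields auPRC 0.946 with an F1-optimal threshold of 0.60.
`scored.tsv` holds one row per variant with its key, region class, every
feature value (`NA` = missing, never imputed) and the final
`INTROME_SCORE`; `scored.vcf` mirrors the same values as INFO fields, and
`eval.report.json` contains the calibrated thresholds, auPRC and
region-stratified recall.

The same API is available as a library, with the classifier exposed as an
sklearn-style estimator:

```python
from splicetree import SpliceImpactTree
model = SpliceImpactTree(min_leaf=2, prune_confidence=0.25).fit(X, y)  # NaN = missing
scores = model.predict_proba(X_new)[:, 1]
```

## Layout

- `src/splicetree/genome.py` — gene models, donor/acceptor region windows
- `src/splicetree/variants.py` — VCF I/O, normalization, filters, complex decomposition
- `src/splicetree/pwm.py`, `features.py` — ESE/ESS scoring and splice-rule features
- `src/splicetree/ingest.py` — external score tables, max-rule, zero-rule
- `src/splicetree/tree.py`, `model.py` — the missing-tolerant decision tree
- `src/splicetree/calibration.py` — PR curves, threshold selection, concordance
- `src/splicetree/simulate.py` — synthetic fixture universe
- `src/splicetree/cli.py` — `splicetree` command

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
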