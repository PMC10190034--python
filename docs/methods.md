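# Methods

## Problem and model

`splicetree` estimates the probability that a small variant (SNV,
insertion, deletion, MNV or insdel) alters pre-mRNA splicing. The central
difficulty is structural missingness: the external predictors the
consensus draws on only operate in parts of the gene body (precomputed
splice-site databases score nothing outside donor/acceptor windows; some
models score SNVs only), so any useful combiner must treat "tool X did
not score this variant" as first-class information rather than imputing
it away.

The combiner is a single C4.5/C5.0-family classification tree with
fractional instance weighting:

* **Split selection.** At each node, candidate thresholds are the
  midpoints of consecutive distinct observed values of a feature. The
  split criterion is the information-gain ratio: the gain is computed on
  the rows where the feature is observed and scaled by the observed
  fraction F = N_known/N; the split information is taken over the
  left/right/missing shares of the node. Splits must leave at least
  `min_leaf` weighted mass on each side and have strictly positive gain.
* **Missing values.** Rows missing the chosen split feature are sent down
  *both* branches with weight multiplied by the observed branch mass
  fractions. Prediction mirrors training: a missing split feature returns
  the mass-weighted mixture of the branch predictions. With complete data
  this reduces exactly to a single root-to-leaf traversal (tested as a
  limit equivalence).
* **Leaf probabilities.** Laplace smoothing (pos+1)/(n+2) over the
  (possibly fractional) class masses, giving continuous scores in (0, 1)
  without degenerate 0/1 leaves.
* **Pruning.** Pessimistic error-based pruning: a subtree collapses to a
  leaf when the upper confidence bound (default confidence 0.25) of the
  leaf's binomial error does not exceed the summed bound of its leaves.
  The bound is obtained from the regularized incomplete beta function and
  accepts real-valued (weighted) counts. `prune_confidence=None`
  disables pruning.
* **Determinism.** Gain-ratio ties break toward the lowest feature-registry
  index, then the lowest threshold. Training and prediction are exact
  functions of (data, parameters); there is no internal randomness.
* **Boosting.** `n_trials > 1` enables an optional AdaBoost.M1-style
  reweighting with log-odds-weighted probability averaging; the default
  is a single tree, which keeps the decision path auditable.

The tree is wrapped as an sklearn-compatible estimator
(`SpliceImpactTree`: `fit` / `predict_proba` / `get_params`, NaN allowed
in inputs) so it composes with sklearn model selection; the rest of the
pipeline is functional because it is not fit/predict-shaped.

## Feature registry

Per variant (missing = NaN, never defaulted):

| group | features | notes |
| --- | --- | --- |
| location | region one-hot (donor/acceptor/exon/intron), `dist_donor`, `dist_acceptor` | donor window 3 exonic + 6 intronic nt; acceptor 3 + 12; windows take precedence over plain exon/intron; minus-strand transcripts mirror |
| ESE/ESS | `pwm_delta_<motif>` for SRSF1, SRSF1 (igM-BRCA2), SRSF2, SRSF5, SRSF6, hnRNP A1 | best-window score delta (alt − ref) on the transcript strand; computed for exonic and near-exonic (≤ motif width into the intron) variants, missing elsewhere |
| dinucleotides | `ag_created/ag_removed/gt_created/gt_removed` | dinucleotide counts over the changed bases ± 1 flank, ref vs alt |
| AGEZ | `in_agez`, `agez_skip_prone`, `bp_distance` | zone = (branchpoint, acceptor AG), both exclusive; an AG created < 15 nt from the branchpoint is the skip-prone subcase, ≥ 15 nt the cryptic-acceptor subcase; without an external branchpoint table the zone start defaults to 44 nt upstream of the 3′SS |
| intron rules | `u12` (missing when no U12 annotation is supplied), `min_intron_violation` | a deletion violates when (intron length − deleted intronic nt) < 45 nt. The 45 nt constant follows the operative definition; it is configurable (`BranchpointConfig.min_intron_nt`) |
| external | per-tool columns (4 SpliceAI-style deltas kept separate, MMSplice Δlogit-PSI, 2 Spliceogen gains, CADD phred, SPIDEX z, dbscSNV ada/rf, branchpoint probability) | the max-over-parts rule applies only to complex-variant decomposition, not to feature construction |

The shipped PWM files are synthetic stand-ins built from the published
consensus motifs (the experimentally derived ESEFinder/iCLIP matrices are
not redistributed); filenames carry `.synthetic.pwm` and the published
ESEFinder score thresholds are kept as metadata defaults. The file format
(`NAME WIDTH ROLE THRESHOLD` + width rows of A/C/G/T weights) makes them
fully swappable for the real matrices.

## Thresholds and calibration

The PR sweep places one point per distinct score (calls are inclusive,
score ≥ threshold). auPRC uses step-wise (rectangular) integration over
recall — PR interpolation conventions differ, so the convention is fixed
and documented; the precision at recall 0 is anchored at the top-ranked
point (this does not affect the step integral). Three operating points
are reported: the F1-optimal threshold (ties toward the higher, more
specific threshold), the threshold at a target specificity (default
0.975; the complementary search at a target sensitivity is also
provided, since either direction may be the stated constraint), and the
lowest threshold reaching a target precision (default 0.95; tools that
never reach it are excluded from region-stratified comparison).
Region-stratified recall reports empty strata as undefined, never 0.
Pipeline defaults for calling (0.61) and high-confidence calling (0.83)
follow the published operating points of the consensus approach.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Genome.** Configurable gene count/geometry (default exons 80–150 nt,
  introns 120–200 nt, alternating strands). Introns carry the donor
  consensus GTAAGT and end in a 44-nt AG-free pyrimidine-rich tail
  (C/T/A, no G) with a branchpoint adenosine 25 nt upstream of the 3′SS —
  a realistic AGEZ in which a single substitution after an A can create a
  cryptic AG. Every exon embeds one SRSF1-consensus ESE at its centre.
* **Variants.** Planted per region class. Informative mode places
  designated positives at disruptive sites (GT/AG hits, ESE-consensus
  disruption, AGEZ AG creation, minimal-intron deletions, plus MNV/insdel
  forms of these) and negatives at neutral sites; uninformative mode
  plants everything at neutral sites. Truth labels come from a latent
  ΔPSI: designated positives draw |N(0.35, 0.15)|, others |N(0, 0.03)|,
  labelled splice-altering at |ΔPSI| ≥ 0.10 — the 10%-transcript-change
  rule used for functionally validated variants. The 0.65 positive
  fraction mirrors the composition of curated functional variant sets.
  By default only the binary label is exported; `export_dpsi=True` adds
  the quantitative value for extension experiments.
* **Tool scores.** Truncated-Gaussian draws whose *only* label dependence
  is a mean shift (`tool_separation`) on the mechanism-relevant column;
  at separation 0 the classes are distributionally identical, which is
  what makes the null-recovery check meaningful. Missingness is
  region-dependent (SPIDEX/dbscSNV never score outside splice-site
  windows or non-SNVs; MMSplice degrades in deep introns), and
  SpliceAI/MMSplice-style tables score the decomposition parts of complex
  variants rather than the complex allele, exercising the max-over-parts
  aggregation.

What passing tests on this generator do **not** show: real tool-score
correlation structure (scores are drawn independently per tool), realistic
motif degeneracy (stand-in PWMs are sharper than experimental matrices),
alternative isoforms, or genome-scale class imbalance. Recovery results
are therefore statements about the pipeline's mechanics (joins, rules,
missing-data handling, calibration), not about clinical accuracy.

## Numerical choices and degenerate inputs

* Internal coordinates are 0-based half-open; VCF positions convert at the
  I/O boundary. Alleles are trimmed suffix-first then prefix to the
  minimal anchored representation, and score-table keys are normalized
  identically so joins are exact.
* Complex-variant decomposition emits anchored VCF-style parts at pos−1
  when the reference anchor base is available (the pipeline path) and
  unanchored empty-allele parts otherwise; both reproduce the alt
  haplotype when re-applied sequentially.
* A position mapping to several transcripts takes the most splice-proximal
  class (donor/acceptor > exon > intron); per-transcript classifications
  are retained. In an intron too short for both windows, the nearer
  splice site wins, ties to the donor. BED gene models carry no exon
  structure, so region classification degrades to in/out-of-region.
* Entropies use log2 with an epsilon guard; a gain must exceed 1e-9 to be
  considered. Scores written to VCF/TSV are formatted with %.6g and the
  round-trip tests compare at that formatted precision.
* Single-class training data, empty feature registries, one-class PR
  inputs and score/label key mismatches raise immediately rather than
  degrading.

## Validation scale

The acceptance workflow uses 2,000 variants (400 donor, 400 acceptor,
600 exonic, 600 intronic) over a 60-gene toy genome, tenfold
cross-validation and a 70/30 train/held-out split — large enough for
stable auPRC/auROC estimates while the whole script completes in well
under a minute on one CPU. The unit suite uses smaller fixtures
throughout.

## Known limitations

* Branchpoints are consumed from an external table (or proxied by a fixed
  18–44 nt window); there is no de novo branchpoint prediction.
* ESE/ESS deltas are restricted to exonic/near-exonic variants; intronic
  splicing regulatory elements are out of scope.
* Site-level only: genotypes, phasing and structural variants are not
  handled.
* The learner is a single tree by design (auditability, native missing
  handling); no comparison against other model families is packaged.
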