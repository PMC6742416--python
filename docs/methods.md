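# Methods

## The model

`gram` predicts whether a non-coding SNV modulates reporter-gene
expression in a given cellular context. The score for variant *i* in
cell/sample *c* is built in three steps.

**Step 1 — universal regulatory activity.** A Random-Forest classifier
F1 maps an allele's TF binding-score vector (B_i1 … B_iN, one score per
TF model, produced upstream by a sequence-to-binding scorer) to
U ∈ [0, 1], the probability that the element drives reporter expression.
The training target is the per-allele activity call from the reporter
counts: fold change assay/control above a cutoff (default 1.5, strict
inequality), optionally gated by a two-sided conditional binomial test
of the assay vs control counts; activity calls from an external
differential-expression analysis can be passed through instead. The allelic contrast enters the final step as

    Odds(i) = | log2( (U_mut / (1 − U_mut)) / (U_wt / (1 − U_wt)) ) |,

with both probabilities clipped away from {0, 1}. The `odds_feature`
function defaults to eps = 1e-6; the training pipeline clips at 1e-3,
the vote-fraction resolution of a few-hundred-tree forest — without this
a single tree's vote flip near saturation produces log-odds swings of
several units that dominate ranking noise.

**Step 2 — cell-type modifier scores.** The per-variant variability
statistic Vodds = sqrt(1/n1 + 1/n2 + 1/n3 + 1/n4) (the delta-method SD of
the count table's log odds ratio) is computed per cell type; variants in
the top/bottom quartiles form the high/low classes. Two Random-Forest
classifiers predict this class: S_b from the reference-allele binding
vector, and S_e from the rank-reordered expression vector, in which
position k holds the expression of the TF with the k-th highest binding
score on the variant's element (ties broken lexicographically by TF id;
ranking key is the reference allele by default, configurable to alt or
elementwise max). Quartile boundaries use linear-interpolation empirical
quantiles with boundary ties labeled inward; both quantiles are
configurable (default 0.25/0.75).

**Step 3 — integration.** An L1-regularized logistic regression combines
the three scores:

    M(i, c) = logistic( b_u·Odds(i) + b_s1·S_b(i, c) + b_s2·S_e(i, c) + b′ ),

with targets the expression-modulating (emVAR) labels: a significant
allelic difference (Fisher exact test on the rounded 2×2 table) AND
|logSkew| > |log2 1.5| ≈ 0.5849, where
logSkew = log2 odds ratio of the table, alternative over reference
(orientation is internal; only the magnitude and label are consumed).
The penalty λ is chosen to minimize mean k-fold cross-validated deviance
over a log-spaced grid (default 25 values in [1e-4, 10^1.5]).

### Numerical choices

* The L1 logistic is solved by accelerated proximal gradient (FISTA)
  with soft-thresholding on the slopes and an unpenalized intercept
  (tolerance 1e-9 on the parameter step, max 50 000 iterations). Off-
  the-shelf solvers misbehave in the penalty-dominated limit, where the
  correct solution is zero slopes and intercept = logit of the class
  prevalence; the proximal solver is exact in both limits and is cross-
  checked against an independent implementation at moderate λ in the
  test suite.
* Step-3 training features are the forests' *out-of-bag* predictions for
  rows the forests were trained on. In-sample forest predictions are
  nearly memorized labels; feeding them to the logistic inflates the
  modifier-arm coefficients and measurably degrades held-out
  performance. Prediction-time features use ordinary forest predictions.
* Forests: 500 trees by default, sqrt(N) features per split, unlimited
  depth, fixed seeds. No class reweighting by default (an optional
  class-weight flag exists).
* Zero counts receive a Haldane–Anscombe pseudocount of 0.5 in logSkew,
  Vodds and fold changes; tables with all counts positive use no
  pseudocount.
* Missing binding scores are imputed with the column (TF) median at read
  time and logged; missing expression values for TFs required by the
  model are imputed with the profile median and flagged on the profile.

## Cross-validation

Folds are drawn at the variant level: a random permutation is chunked
into k nearly equal folds, and both alleles plus every per-cell row of a
variant share its fold. For each fold, *all* stages — the activity
forest, the quartile boundaries of the modifier labels, both modifier
forests, and the step-3 logistic — are re-fit on the remaining variants
only; held-out predictions are concatenated and scored once. AUROC is
the Mann–Whitney statistic normalized by n_pos·n_neg with half credit
for ties; AUPRC uses step-interpolated precision–recall integration
(both equal scikit-learn's conventions and are cross-checked against it).
If a candidate fold assignment leaves a training partition single-class,
the assignment is redrawn with the next seed (at most 10 attempts,
logged). `cross_validate(..., submodel_scope="full")` is a deliberate
leakage diagnostic — submodels fit once on all variants — used to
demonstrate the inflation that per-step fold leakage causes.

## The synthetic-data generator

The generator emulates the package's input contract directly — binding
scores, expression profiles and count tables — rather than sequence.

* **Binding.** N TF models score V variants; the n_signal TFs are the
  high-affinity regulators of these elements, with reference scores
  elevated by 1.5 over the N(0, 1) background so they concentrate at the
  top of per-variant binding rankings. With probability 0.5 a variant
  perturbs its dominant (strongest-bound) signal TF — a clear motif
  disruption or gain, |delta| ~ N(1.2, 0.4) with random sign — and it
  always perturbs 3 random background TFs with weak N(0, 0.5) wobble.
* **Expression.** Each cell type expresses a complementary subset of the
  signal TFs (signal TF s is "on" in cell s mod n_cells: log-scale
  expression ~ N(6, 0.5) on, N(2, 0.5) off); background TFs share a
  per-TF baseline N(4, 1) across cell types plus N(0, 0.3) cell noise.
  An unexpressed signal TF's regulatory gate is 1 − expression_coupling
  (default 0.1).
* **Counts.** Reference-allele activity is logistic in the gated maximum
  signal binding score, centered per cell and scaled by effect_size
  (default 0.5); the alternative allele shifts the activity log-odds by
  skew_effect (default 1.5) times the sum of gated signal-TF deltas.
  Assay counts are negative-binomial around depth·activity and control
  counts around depth·(1 − activity) (depth 500, dispersion 0.01;
  Poisson at dispersion 0), so the expected log odds ratio of the table
  equals the latent allelic logit shift. The default effect sizes place
  baseline activity near the detection boundary, so a genuine
  expression-modulating event typically flips detectable activity — the
  premise of an activity-based universal score. The true emVAR label is
  defined on the latent (noise-free) log2 skew against the 0.5849
  threshold, so label noise is controlled solely by depth and
  dispersion. Setting skew_effect = 0 (`null_config`) decouples the
  deltas from the counts entirely: no true positives exist and observed
  labels are pure assay noise.
* **Cohorts (fine-mapping).** A cohort plants one causal variant whose
  element depends on a single clearly dominant high-affinity site
  (reference score ≥ 3.5, other signal TFs capped at sub-average
  affinity so no redundant site buffers the loss); the alternative
  allele breaks that motif (−2.5). Other variants carry only N(0, 0.1)
  background deltas. Genotypes are binomial with MAF 0.3; the target
  gene's expression is 1.5·dosage + N(0, 0.5); every sample expresses
  the signal TFs.

What the generator does **not** emulate: barcode- and replicate-level
MPRA structure (dispersion shrinkage, barcode collapsing), sequence-level
motif effects, linkage disequilibrium between cohort variants, chromatin
context, and correlated TF co-expression. Passing tests therefore show
that the implementation recovers the signal structure the model assumes;
they do not certify performance on real assay data.

## Problem sizes for the reproduction script

`scripts/acceptance.py` runs: the strong scenario at V = 2000 with
10-fold CV and 200-tree forests; the null scenario at V = 1000; the
leakage canary at V = 400 with 5-fold CV and 150 trees; step-3 recovery
on n = 5000 simulated rows; the Vodds Monte-Carlo check on 200 000
Poisson resamples; and fine-mapping recovery with a bundle trained at
V = 800 (300 trees) scored on 10 cohorts of 50 variants × 60 samples.
These sizes were chosen to keep a complete run on one CPU comfortably
inside a coffee break while leaving every comparison well-powered.

## Known limitations

* S_b is cell-independent at prediction time (binding features only);
  all cell discrimination flows through the expression arm.
* The activity forest cannot extrapolate beyond the binding-score range
  seen in training; binding-gain variants far outside that range are
  scored conservatively.
* Activity and allelic-skew significance use conditional binomial and
  Fisher-exact count tests on replicate-averaged counts; they do not
  model replicate-level dispersion. Externally computed activity calls
  and logSkew values can be supplied to bypass both.
* The fine-mapping ranking is the mean score across samples; no
  LD-aware posterior is computed.
* Indels, multi-allelic sites, strand-aware scoring and liftover are out
  of scope; sequences are reported on the forward strand.
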