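# Methods

## The model

For a test patient with expression vector *x* and a labelled training cohort
(X, y), similarity to each training patient is the Pearson correlation
coefficient (PCC) of the two full gene-expression vectors. A *personalized
classifier* (PC) at threshold *t* is an L1-penalized logistic regression
fitted only on the training patients with |PCC| > *t* (strict inequality;
"signed" mode). The "positive-only" mode, kept as an ablation, restricts to
PCC > *t*. PCMT averages the PC poor-class probabilities over an inclusive
arithmetic grid of thresholds, by default 0.15 to 0.275 in steps of 0.025
(six thresholds): with ~1600 training patients this grid spans personalized
training sets from roughly subtype-sized down to close-neighbor-sized, which
is the population-size uncertainty the ensemble is meant to absorb.

Models are transient: nothing is pre-trained, and each test patient induces
six small logistic fits. The poor/metastatic outcome is the positive class
in every probability and every AUC.

### Base learner and fallback

The logistic fits use the liblinear solver with a pure L1 penalty, inverse
regularization strength C = 1.0, tolerance 1e-4, at most 1000 iterations and
a pinned solver shuffle seed (liblinear permutes coordinates internally;
pinning makes fits bit-reproducible). No per-feature standardization is
applied beyond whatever normalization the input matrix carries. Class
weights are uniform despite outcome imbalance.

If a selection is empty or single-class, no discriminative model exists for
that (patient, threshold) pair; the PC then returns the poor-class
prevalence of the full training cohort. This keeps the ensemble average
defined for every input without inventing neighbors; fallbacks are counted
and logged. In coefficient-based feature scoring, fallback PCs contribute
zero coefficient vectors.

### Comparators

The pooled comparators are a single L1-logistic fit on the whole training
cohort (feature importance = |coefficients|) and a 100-tree random forest
(impurity importances), seeded. The RF hyperparameters beyond tree count
are library defaults and deliberately non-normative.

## Evaluation harness

Three schemes, all scoring with ROC-AUC (Mann–Whitney convention, ties 1/2):

* **Repeated stratified 5-fold CV** — 8 repeats by default, giving 40 paired
  AUCs per model. Folds are class-stratified (a choice; the fold protocol is
  otherwise under-determined) and shared by all models within a repeat so
  paired t-tests across folds are valid. With stratified folds, a fold can
  lack a class only when a class has fewer members than folds — a condition
  re-drawing cannot repair — so such folds score NaN and are logged rather
  than re-drawn.
* **Leave-one-study-out CV** — one AUC per held-out study; single-class
  studies score NaN and are excluded from paired tests.
* **Leave-one-out CV** — one probability per sample, one pooled AUC per
  model; the stored probability vectors feed subtype-restricted AUCs
  (slice the pooled LOOCV probabilities by subtype, score each slice) and
  the per-subtype feature rankings.

Paired comparisons use a two-sided paired t-test. A zero-variance difference
vector is degenerate: p = 1.0 when the mean difference is also zero, NaN (a
deliberate flag) otherwise; both cases detected with a relative tolerance of
1e-10 because AUC vectors arrive through floating-point arithmetic.

## Feature-robustness statistic

The cohort is split into two disjoint, class-stratified halves (as equal as
parity allows), each model scores every gene on each half, and the top-X
lists are compared. X is chosen per expected-overlap level *k* as the
largest integer with X²/G ≤ k (G = total genes), because two uniform random
X-subsets of G genes share X²/G features in expectation; the **overlap
ratio** |top_A ∩ top_B| / k is therefore 1 for an uninformative ranking and
grows with selection stability. For G = 12 750 and k ∈ {5, 10, 20, 30, 50}
this gives X = 252, 357, 504, 618, 798.

PC feature scores on a half are the mean |coefficient| over leave-one-out
personalized classifiers at threshold 0.175 (intercepts excluded — they are
not gene features). The PC-random control repeats this with uniformly random
neighbor sets of exactly the same per-sample sizes, isolating the
contribution of correlation-based selection from that of averaging many
models. Pooled LR/RF contribute one fit per half.

Ties in the top-X cut are broken by a seeded random permutation drawn
independently for each half (reproducible given the run seed). A
deterministic tie order shared by both halves was rejected: a single sparse
fit typically has fewer positive scores than X at the deeper levels, and any
shared tie order would then fabricate overlap in exactly the models the
statistic is supposed to penalize. A zero-score gene still never displaces a
positive-score gene.

The concentration statistic reports the share of total |score| mass carried
by the top fraction of genes (⌈fraction·G⌉ genes), a scale-invariant summary
of how peaked an importance vector is.

## Synthetic cohorts

### Default heterogeneous cohort (`generate_cohort`)

Defaults: 400 patients × 500 genes, 3 latent subtypes in equal proportion,
poor-outcome prevalence target 0.28 (the imbalance of large five-year
metastasis cohorts), 4 studies with additive N(0, 0.3²) per-gene mean
shifts, unit-variance Gaussian gene noise.

* **Subtype geometry.** Centroids sit at the vertices of a regular simplex
  embedded through a random orthonormal basis; pairwise centroid inner
  products are negative (−1/(K−1) times the norms), so members of one
  subtype correlate positively and across subtypes negatively — the
  correlation block structure personalized selection relies on. Subtypes
  have unequal compactness: per-subtype multipliers on `centroid_scale`
  (default linspace 1.4 → 0.6) make some subtypes tight and some loose, as
  real intrinsic subtypes are. This spread matters beyond realism: patients
  of a loose subtype find few strongly positively correlated neighbors at
  the upper thresholds, and it is exactly there that admitting strongly
  anti-correlated patients from tighter subtypes keeps their personalized
  training sets usable. With uniform compactness, positive-only selection
  never starves and the signed-mode advantage cannot appear at any scale.
* **Outcome rule.** The log-odds of a poor outcome mixes two linear
  components: a **shared block** (10 genes, effect 0.6) whose coefficients
  are identical in every subtype — this is what makes anti-correlated
  patients genuinely informative, since their labels constrain the same
  coefficients from the opposite side of expression space — and a
  **reversed block** (20 genes, effect 0.6) whose per-gene signs flip
  between subtypes, centered against the subtype proportions so the
  proportion-weighted mean coefficient is exactly zero (`shared_reversed`
  mode, the default). Pooling captures the shared block but faces exact
  cancellation on the reversed one, so the population-optimal pooled linear
  model stays ≥ 0.05 in AUC below the oracle that knows each patient's
  subtype rule (verified out-of-sample in the tests). Sign columns drawn
  identical across all subtypes carry no effect after centering, so a few
  nominal reversed genes per draw are inactive. A `disjoint` mode gives
  each subtype its own signal block instead, for experiments that need
  subtype-specific markers.
* **Calibration and oracle.** The intercept is solved (Brent) so the mean
  generating probability matches the prevalence target; labels are Bernoulli
  draws. The true probabilities, coefficient matrix and signal-gene indices
  are retained in `dataset.attrs` so tests can compare fitted models against
  the Bayes-optimal ranking.
* **Effect size.** Effects of 0.6 logit units per unit expression put the
  Bayes AUC near 0.95 — strong enough that model differences are
  attributable to modelling, weak enough that labels stay stochastic.

A paired-cohort variant draws two cohorts from one generating process and
passes the second through a strictly monotone distortion (per-gene gain and
offset, optional cubic term, per-sample gain and offset emulating array
intensity variation) plus optional gene dropout — the inputs that the
common-gene intersection and joint quantile normalization steps exist to
repair. Per-sample distortions are the component quantile normalization
removes exactly; per-gene distortions are deliberately outside its reach.

### Feature-stability cohort (`generate_feature_stability_cohort`)

Split-half feature stability at desk scale needs structure that the default
cohort does not emphasize. Three ingredients are supplied explicitly,
each mirroring a property of real expression data:

1. **Correlated signal modules** (15 modules × 8 genes at defaults; a shared
   N(0,1) module factor plus N(0, 0.6²) gene noise). Any single sparse fit
   picks an arbitrary member of each module, whereas score vectors averaged
   over many fits spread mass across whole modules — the mechanism that
   separates fit-averaged scores (PC, PC-random) from single-fit scores
   (pooled LR/RF).
2. **A decaying effect spectrum** (module effect 1.5 · exp(−j/8)), so the
   ranking has a well-defined head at every list depth instead of an
   exchangeable plateau whose order is pure noise.
3. **Sign-reversed module effects with no prevalence leak**: module effects
   flip sign between subtypes (proportion-centered to a pooled mean of
   exactly zero) and the log-odds is taken on the *deviation* from the
   subtype centroid, so every subtype has the same outcome rate and pooled
   models cannot substitute subtype membership for signal. The centroid
   scale is lowered to 0.65 so cross-subtype |PCC| (≈ 0.15) stays below the
   0.175 robustness threshold while within-subtype PCC (≈ 0.30) stays
   above it, making personalized selections subtype-enriched
   (≈ 73% same-subtype at defaults).

Under these conditions the overlap-ratio ordering PC > PC-random >
pooled LR/RF holds at every expected-overlap level (medians over 5 seeds ×
5 repeats). Exploration of flatter regimes showed why they fail at this
scale: with ~150-sample halves and i.i.d. noise genes, per-gene effects
below roughly 3/√n of the total logit scale are statistically unresolvable
and every model's ratio collapses to ≈ 1. The full-size phenomenon rests on
cohorts five times larger.

### What the generator does not emulate

Marginal expression distributions of real platforms, probe-level artefacts,
realistic subtype proportions or PAM50-like marker structure, censoring, and
correlated study effects beyond additive mean shifts. Passing tests
demonstrate that the implementation behaves correctly in the regimes the
method targets, not that the same margins will appear on any particular real
cohort.

## Study conditions used by the end-to-end checks

Chosen once as desk-scale study conditions and recorded here:

* Heterogeneity recovery and the signed/positive-only ablation: the default
  cohort (400 × 500, 3 subtypes), LOOCV, seeds 0–4; medians over seeds.
  This is the expensive part of the suite (fifteen LOOCV sweeps); it runs
  once per session and feeds every heterogeneity assertion.
* Harness cardinality: 200 × 100 cohort, 8 × 5-fold CV.
* Robustness ordering: the feature-stability cohort (300 × 300), 5 split
  repeats per seed, seeds 0–4, levels {5, 10, 20, 30, 50}.
* Chance normalization of the overlap ratio: 200 random draws at
  G = 12 750, level 5.

## Numerical choices and edge cases

* Strict ">" at every selection threshold; samples exactly at the threshold
  are excluded.
* PCC is undefined for constant profiles; these are rejected with the
  offending sample named. Computed values are clipped to [−1, 1] against
  rounding drift.
* Quantile normalization maps every sample to the mean-quantile reference of
  the pooled cohorts; tied values within a sample receive the mean of the
  reference values at their tied ranks.
* The threshold grid is generated by integer stepping (not repeated
  addition) and rounded to 12 decimals so the inclusive endpoint is stable.
* The PFI label rule: poor requires the progression event flag; exactly
  5 years with an event counts as poor ("within five years" is inclusive);
  progression-free beyond 5 years is good; censored before 5 years is
  undecided, and undecided samples are dropped before modelling.
* Ranking ties (mean |coefficient|) break lexicographically by gene id;
  all-zero genes can never outrank a gene with positive score.
* The pooled gene ranking averages |coefficients| over the n leave-one-out
  fits by default; a single full-cohort fit is available via
  `loocv_average=False`.

## Known limitations

* Runtime scales linearly in test patients × thresholds; with no pre-trained
  model, batch prediction over large cohorts is the dominant cost.
* The degenerate-selection fallback returns a constant; cohorts where many
  patients select empty neighbor sets (very high thresholds, tiny cohorts)
  converge to prevalence predictions and AUC 0.5.
* Cross-platform transfer repairs only what sample-wise quantile
  normalization can express; per-gene distortions (probe effects) are out of
  scope, matching the method's minimal cross-dataset normalization stance.
* Only Pearson correlation ships as the similarity measure; the selection
  layer is a pure function of a precomputed correlation profile, so other
  measures can be slotted in upstream.
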