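# pcmt — personalized classifiers with multiple correlation thresholds

`pcmt` predicts binary clinical outcomes (the motivating application is
five-year breast-cancer metastasis) from gene-expression profiles in
**heterogeneous** cohorts. Tumor cohorts mix molecular subtypes whose
outcome-driving genes differ — a single model trained on everyone averages
over conflicting signals. Instead of one model, `pcmt` builds a *personalized
classifier* (PC) for every test patient:

1. compute the Pearson correlation coefficient (PCC) between the test
   patient's expression vector and every training patient's;
2. keep the training patients with |PCC| > *t* — both the most similar and
   the most *dissimilar* patients, since members of other subtypes are
   often strongly anti-correlated and add useful diversity;
3. fit an L1-penalized logistic regression on that subset and read off the
   poor-outcome probability for the test patient.

Because the right *t* depends on the (unknown) size of the patient's latent
subtype, the **PCMT** ensemble averages the PC probabilities over a grid of
thresholds, by default `0.15, 0.175, …, 0.275`:

```
p_PCMT(x) = (1/|T|) · Σ_{t ∈ T} p_PC(x; t)
```

The package also ships a full evaluation harness (repeated
stratified 5-fold CV, leave-one-study-out CV, leave-one-out CV, ROC-AUC,
paired t-tests, subtype-restricted AUC), a split-half feature-robustness
statistic, per-subtype gene rankings, cross-dataset preparation (common-gene
intersection, mean centering, joint quantile normalization, PFI-based
labelling), and a synthetic cohort generator with latent subtypes so every
analysis is testable without external data.

Intended users: computational biologists benchmarking outcome predictors on
expression cohorts, and methodologists studying personalized/similarity-
based model selection.

## Worked example

```python
import numpy as np
from pcmt import (GeneratorConfig, PCMTClassifier, PooledLogistic,
                  generate_cohort, run_loocv)

# 400 patients, 500 genes, 3 latent subtypes of unequal compactness whose
# outcome rule mixes shared and sign-reversed gene effects; ~28% poor
# outcomes across 4 studies
cohort = generate_cohort(GeneratorConfig(seed=0))

report = run_loocv(cohort, {
    "pcmt": PCMTClassifier(),        # thresholds 0.15..0.275, signed mode
    "pooled_lr": PooledLogistic(),   # one sparse logistic fit on everyone
})
for (model, _), score in report.auc_scores.items():
    print(f"{model:>10}: LOOCV AUC = {score:.3f}")
```

Output:

```
      pcmt: LOOCV AUC = 0.808
 pooled_lr: LOOCV AUC = 0.756
```

The pooled model learns the shared effects but faces sign-cancellation on
the subtype-specific ones and lands at AUC 0.756, while PCMT — training each
patient's model on correlation-selected neighbors — reaches 0.808 (the
cohort's Bayes-optimal ranking sits at AUC 0.961, available from
`cohort.attrs["true_probs"]`).

The same workflows are available from the shell:

```bash
pcmt simulate --seed 1 --out cohort/
pcmt evaluate --config run.yaml            # 5fcv | loso | loocv
pcmt robustness --config run.yaml --levels 5,10,20,30,50 --repeats 20
pcmt rank --config run.yaml --threshold 0.2 --top-k 20
```

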