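import numpy as np
import pytest

from pcmt.data import ExpressionDataset
from pcmt.simulate import GeneratorConfig, generate_cohort


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Deterministic 8-sample, 6-gene cohort with both classes."""
    rng = np.random.default_rng(42)
    return ExpressionDataset(
        matrix=rng.normal(size=(8, 6)),
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{i}" for i in range(8)],
        labels=[0, 1, 0, 1, 0, 1, 0, 1],
        subtypes=["a", "a", "a", "a", "b", "b", "b", "b"],
        studies=["x", "x", "y", "y", "x", "x", "y", "y"],
    )


@pytest.fixture(scope="session")
def small_cohort() -> ExpressionDataset:
    """Small synthetic cohort with the default heterogeneity structure."""
    return generate_cohort(
        GeneratorConfig(n_samples=120, n_genes=80, n_subtypes=3, n_studies=3, seed=7)
    )


@pytest.fixture(scope="session")
def heterogeneity_runs():
    """LOOCV AUCs of PCMT (both selection modes) and the pooled sparse
    logistic model on the default reversed-effect cohorts, one run per seed.

    This is the package's main end-to-end experiment (the expensive part of
    the suite); it is computed once per session and shared by every test
    that asserts something about the heterogeneity regime.
    """
    from pcmt.evaluation import run_loocv
    from pcmt.models import PCMTClassifier, PooledLogistic

    runs = []
    for seed in range(5):
        d = generate_cohort(GeneratorConfig(seed=seed))
        rep = run_loocv(
            d,
            {
                "pcmt_signed": PCMTClassifier(mode="signed"),
                "pcmt_positive": PCMTClassifier(mode="positive_only"),
                "pooled_lr": PooledLogistic(),
            },
        )
        runs.append(
            {
                name: rep.auc_scores[(name, "all")]
                for name in ("pcmt_signed", "pcmt_positive", "pooled_lr")
            }
        )
    return runs


@pytest.fixture(scope="session")
def separable_cohort() -> ExpressionDataset:
    """Homogeneous cohort with one strong global signal (easy problem)."""
    rng = np.random.default_rng(3)
    n, g = 60, 30
    labels = np.tile([0, 1], n // 2)
    x = rng.normal(size=(n, g))
    x[:, 0] += 3.0 * labels  # single informative gene
    return ExpressionDataset(
        matrix=x,
        gene_ids=[f"g{i}" for i in range(g)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
    )
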