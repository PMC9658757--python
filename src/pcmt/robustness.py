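"""Split-half robustness of feature selection.

The cohort is repeatedly partitioned into two disjoint halves; each model
produces a feature-importance score vector per half, the top-X features are
taken from each, and the overlap is compared with what two random X-subsets
of the gene universe would share by chance. With X chosen so that the
chance-expected overlap is a target level k (X = floor(sqrt(n_genes * k)),
since the expected overlap of two random X-subsets is X^2 / n_genes), the
overlap ratio |top_A ∩ top_B| / k equals 1 in expectation for an
uninformative ranking and grows with selection stability.

Model importance scores:

* ``pc`` — within each half, leave-one-out personalized classifiers at a
  fixed PCC threshold (default 0.175); score = mean |coefficient| over the
  half's samples (fallback PCs contribute zero vectors).
* ``pc_random`` — the control: same per-sample training-set sizes as the
  true PC, but the neighbors are drawn uniformly at random.
* ``pooled_lr`` / ``pooled_rf`` — one model per half; |coefficients| or
  impurity importances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .models import PooledLogistic, PooledRandomForest
from .selection import pearson_cross_profile, select_training_subset

logger = logging.getLogger(__name__)

__all__ = [
    "RobustnessReport",
    "top_feature_count",
    "overlap_ratio",
    "top_features",
    "pc_feature_scores",
    "pc_random_feature_scores",
    "run_robustness",
    "concentration_share",
    "DEFAULT_LEVELS",
    "ROBUSTNESS_THRESHOLD",
]

#: Expected-overlap levels used throughout the robustness analysis.
DEFAULT_LEVELS = (5, 10, 20, 30, 50)
#: PCC threshold of the single PC used for robustness evaluation.
ROBUSTNESS_THRESHOLD = 0.175


def top_feature_count(total_features: int, expected_overlaps: int) -> int:
    """Top-list size X whose chance overlap between two random X-subsets is
    the given level: the largest integer with X^2 / total <= expected."""
    if total_features < 1 or expected_overlaps < 1:
        raise ValueError("total_features and expected_overlaps must be >= 1")
    x = math.isqrt(total_features * expected_overlaps)
    return x


def overlap_ratio(top_a: set, top_b: set, expected_overlaps: int) -> float:
    """Observed shared top features divided by the chance-expected count."""
    if len(top_a) != len(top_b):
        raise ValueError("top-feature sets must have equal size")
    if expected_overlaps < 1:
        raise ValueError("expected_overlaps must be >= 1")
    return len(set(top_a) & set(top_b)) / expected_overlaps


def top_features(
    scores: np.ndarray,
    gene_ids: np.ndarray,
    k: int,
    rng: Optional[np.random.Generator] = None,
) -> set:
    """Ids of the k highest-scoring genes.

    Ties are broken by a random permutation (seeded by the caller) so that a
    model with fewer than k distinct positive scores cannot share a
    deterministic tail ordering with another partition and fabricate overlap;
    without an rng, ties fall back to gene-id order. A zero-score gene never
    displaces a positive-score gene.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if rng is None:
        order = sorted(range(n), key=lambda i: (-scores[i], str(gene_ids[i])))
    else:
        jitter = rng.permutation(n)
        order = sorted(range(n), key=lambda i: (-scores[i], jitter[i]))
    return {gene_ids[i] for i in order[:k]}


def concentration_share(scores: np.ndarray, top_fraction: float) -> float:
    """Share of total importance mass carried by the top fraction of features."""
    scores = np.asarray(scores, dtype=float)
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if (scores < 0).any():
        raise ValueError("scores must be nonnegative")
    total = scores.sum()
    if total == 0:
        raise ValueError("all-zero scores carry no mass to concentrate")
    k = math.ceil(top_fraction * len(scores))
    top = np.sort(scores)[::-1][:k]
    return float(top.sum() / total)


def _loocv_coefficient_scores(
    partition: ExpressionDataset,
    selections: list[np.ndarray],
    regularization_strength: float = 1.0,
) -> np.ndarray:
    """Mean |coefficient| over per-sample PCs given precomputed neighbor sets."""
    from .models import fit_l1_logistic, SingleClassError

    n = partition.n_samples
    total = np.zeros(partition.n_genes)
    n_fallback = 0
    for i in range(n):
        idx = selections[i]
        labels = partition.labels[idx] if len(idx) else np.empty(0, dtype=int)
        if len(idx) == 0 or len(np.unique(labels)) < 2:
            n_fallback += 1  # fallback PC: zero coefficient vector
            continue
        model = fit_l1_logistic(
            partition.matrix[idx], labels, regularization_strength
        )
        total += np.abs(model.coefficients)
    if n_fallback:
        logger.info("%d/%d PCs hit the degenerate-selection fallback", n_fallback, n)
    return total / n


def _pc_selections(
    partition: ExpressionDataset, threshold: float, mode: str = "signed"
) -> list[np.ndarray]:
    """Leave-one-out PCC neighbor sets within a partition (self excluded)."""
    pcc = pearson_cross_profile(partition.matrix, partition.matrix)
    selections = []
    for i in range(partition.n_samples):
        others = np.delete(np.arange(partition.n_samples), i)
        sel = select_training_subset(pcc[i, others], threshold, mode)
        selections.append(others[sel.selected_indices])
    return selections


def pc_feature_scores(
    partition: ExpressionDataset, threshold: float = ROBUSTNESS_THRESHOLD
) -> np.ndarray:
    """PC feature-importance vector for one partition.

    For each sample, a personalized classifier at ``threshold`` is trained on
    the remaining partition samples; the score is the mean of |coefficients|
    across samples (intercepts excluded; fallback PCs contribute zeros).
    """
    return _loocv_coefficient_scores(partition, _pc_selections(partition, threshold))


def pc_random_feature_scores(
    partition: ExpressionDataset,
    rng: np.random.Generator,
    threshold: float = ROBUSTNESS_THRESHOLD,
) -> np.ndarray:
    """Random-neighbor control: PCs with uniformly random training sets of the
    same per-sample sizes as the true PC selections."""
    true_sel = _pc_selections(partition, threshold)
    selections = []
    for i, sel in enumerate(true_sel):
        others = np.delete(np.arange(partition.n_samples), i)
        k = len(sel)
        selections.append(rng.choice(others, size=k, replace=False) if k else sel)
    return _loocv_coefficient_scores(partition, selections)


@dataclass
class RobustnessReport:
    """Overlap ratios per model, expected-overlap level and repeat."""

    expected_overlap_levels: list[int]
    top_feature_counts: list[int]
    n_repeats: int
    overlap_ratios: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    seed: Optional[int] = None

    def mean_ratio(self, model: str, level: int) -> float:
        return float(np.mean(self.overlap_ratios[(model, level)]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, level), ratios in self.overlap_ratios.items():
            for rep, r in enumerate(ratios):
                rows.append(
                    {"model": model, "level": level, "repeat": rep, "ratio": r}
                )
        return pd.DataFrame(rows)


def _stratified_half_split(
    labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint halves, as equal as parity allows, class-stratified."""
    half_a: list[int] = []
    half_b: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        cut = len(idx) // 2
        half_a.extend(idx[:cut])
        half_b.extend(idx[cut:])
    return np.sort(np.array(half_a)), np.sort(np.array(half_b))


def run_robustness(
    d: ExpressionDataset,
    models: Sequence[str] = ("pc", "pc_random", "pooled_lr", "pooled_rf"),
    levels: Sequence[int] = DEFAULT_LEVELS,
    n_repeats: int = 20,
    seed: int = 0,
    threshold: float = ROBUSTNESS_THRESHOLD,
) -> RobustnessReport:
    """Split-half overlap-ratio analysis over repeated random partitions.

    Each repeat draws a fresh class-stratified half-split; each model scores
    features on both halves independently; ratios are recorded at every
    expected-overlap level.
    """
    if d.n_samples < 8:
        raise ValueError("need at least 8 samples for split-half analysis")
    levels = list(levels)
    counts = [top_feature_count(d.n_genes, k) for k in levels]
    if max(counts) > d.n_genes:
        raise ValueError("top-feature count exceeds the number of genes")
    rng = np.random.default_rng(seed)
    report = RobustnessReport(
        expected_overlap_levels=levels,
        top_feature_counts=counts,
        n_repeats=n_repeats,
        overlap_ratios={(m, k): np.empty(n_repeats) for m in models for k in levels},
        seed=seed,
    )
    for rep in range(n_repeats):
        idx_a, idx_b = _stratified_half_split(d.labels, rng)
        halves = (d.subset_samples(idx_a), d.subset_samples(idx_b))
        for model in models:
            scores = []
            for half in halves:
                if model == "pc":
                    s = pc_feature_scores(half, threshold)
                elif model == "pc_random":
                    s = pc_random_feature_scores(half, rng, threshold)
                elif model == "pooled_lr":
                    s = PooledLogistic().fit(half).feature_importances()
                elif model == "pooled_rf":
                    s = (
                        PooledRandomForest(seed=int(rng.integers(2**31)))
                        .fit(half)
                        .feature_importances()
                    )
                else:
                    raise ValueError(f"unknown robustness model {model!r}")
                scores.append(s)
            tie_rngs = [
                np.random.default_rng(rng.integers(2**31)) for _ in scores
            ]
            for k, x in zip(levels, counts):
                tops = [
                    top_features(s, d.gene_ids, x, tie_rng)
                    for s, tie_rng in zip(scores, tie_rngs)
                ]
                report.overlap_ratios[(model, k)][rep] = overlap_ratio(
                    tops[0], tops[1], k
                )
    return report
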