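"""Per-subtype and pooled top-gene ranking from LOOCV coefficient averages.

Personalized classifiers produce one sparse coefficient vector per patient
(via leave-one-out over the cohort at a fixed PCC threshold, default 0.2).
Averaging |coefficients| within each intrinsic subtype yields a
subtype-specific gene ranking — something a single pooled model cannot
provide. The pooled comparator ranking averages |coefficients| over the
LOOCV fits of the cohort-wide L1-logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .models import fit_l1_logistic
from .robustness import _loocv_coefficient_scores, _pc_selections

logger = logging.getLogger(__name__)

__all__ = ["SubtypeGeneRanking", "subtype_rankings", "pooled_ranking", "RANKING_THRESHOLD"]

#: Default PCC threshold for coefficient generation in top-gene analysis.
RANKING_THRESHOLD = 0.2


@dataclass(frozen=True)
class SubtypeGeneRanking:
    """Ordered top genes for one subtype with their mean-|coefficient| scores."""

    subtype: str
    ranked_genes: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        if len(self.ranked_genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if any(b > a for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be non-increasing")
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError("duplicate genes in ranking")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subtype": self.subtype,
                "rank": np.arange(1, len(self.ranked_genes) + 1),
                "gene_id": self.ranked_genes,
                "score": self.scores,
            }
        )


def _rank_top(scores: np.ndarray, gene_ids: np.ndarray, top_k: int, subtype: str) -> SubtypeGeneRanking:
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], str(gene_ids[i])))
    top = order[:top_k]
    return SubtypeGeneRanking(
        subtype=subtype,
        ranked_genes=tuple(str(gene_ids[i]) for i in top),
        scores=tuple(float(scores[i]) for i in top),
    )


def _per_sample_pc_coefficients(
    d: ExpressionDataset, threshold: float
) -> np.ndarray:
    """|coefficient| vector per sample from LOOCV personalized classifiers.

    Fallback PCs (empty or single-class neighbor sets) contribute zeros.
    """
    selections = _pc_selections(d, threshold)
    coefs = np.zeros((d.n_samples, d.n_genes))
    for i, idx in enumerate(selections):
        labels = d.labels[idx] if len(idx) else np.empty(0, dtype=int)
        if len(idx) == 0 or len(np.unique(labels)) < 2:
            continue
        model = fit_l1_logistic(d.matrix[idx], labels)
        coefs[i] = np.abs(model.coefficients)
    return coefs


def subtype_rankings(
    d: ExpressionDataset,
    threshold: float = RANKING_THRESHOLD,
    top_k: int = 20,
) -> dict[str, SubtypeGeneRanking]:
    """Top-k gene ranking per subtype from personalized-classifier coefficients.

    LOOCV over the full cohort at the given PCC threshold produces one
    coefficient vector per patient; each subtype's ranking is the mean
    |coefficient| over its members. Ties break lexicographically by gene id;
    subtypes with fewer than two members are excluded with a warning.
    """
    if d.subtypes is None:
        raise ValueError("dataset has no subtype annotation")
    if top_k > d.n_genes:
        raise ValueError("top_k exceeds the number of genes")
    coefs = _per_sample_pc_coefficients(d, threshold)
    out: dict[str, SubtypeGeneRanking] = {}
    for st in pd.unique(d.subtypes):
        mask = d.subtypes == st
        if mask.sum() < 2:
            logger.warning("subtype %s has < 2 members; excluded from ranking", st)
            continue
        out[str(st)] = _rank_top(coefs[mask].mean(axis=0), d.gene_ids, top_k, str(st))
    return out


def pooled_ranking(
    d: ExpressionDataset, top_k: int = 20, loocv_average: bool = True
) -> SubtypeGeneRanking:
    """Top-k genes of the pooled L1-logistic comparator.

    Default scores are the mean |coefficient| across the n leave-one-out fits;
    ``loocv_average=False`` uses a single full-cohort fit instead.
    """
    if top_k > d.n_genes:
        raise ValueError("top_k exceeds the number of genes")
    if loocv_average:
        all_idx = np.arange(d.n_samples)
        total = np.zeros(d.n_genes)
        for i in range(d.n_samples):
            idx = np.delete(all_idx, i)
            model = fit_l1_logistic(d.matrix[idx], d.labels[idx])
            total += np.abs(model.coefficients)
        scores = total / d.n_samples
    else:
        scores = np.abs(fit_l1_logistic(d.matrix, d.labels).coefficients)
    return _rank_top(scores, d.gene_ids, top_k, "all")
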