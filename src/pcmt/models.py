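"""Base learners, the personalized classifier (PC) and its multi-threshold
ensemble (PCMT), plus the pooled comparator models.

A PC for one test patient is an L1-penalized logistic regression trained only
on the training patients whose |PCC| with that patient exceeds a threshold.
PCMT averages the PC predicted probabilities over a grid of thresholds,
covering the uncertainty in how large the patient's latent subtype is.
Models are transient: nothing is pre-trained, every test sample gets its own
set of classifiers.

The poor/metastatic outcome is the positive class everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .data import ExpressionDataset
from .selection import (
    DEFAULT_THRESHOLDS,
    SelectionResult,
    pearson_cross_profile,
    pearson_profile,
    select_training_subset,
)

__all__ = [
    "FittedLinearModel",
    "PredictionRecord",
    "SingleClassError",
    "fit_l1_logistic",
    "personalized_probability",
    "pcmt_predict",
    "PCMTClassifier",
    "PooledLogistic",
    "PooledRandomForest",
]


class SingleClassError(ValueError):
    """Training labels contain a single class; no discriminative model exists."""


@dataclass(frozen=True)
class FittedLinearModel:
    """Sparse linear decision function from an L1-logistic fit."""

    coefficients: np.ndarray
    intercept: float
    training_sample_count: int

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of the poor class for each row of ``x``."""
        z = np.atleast_2d(x) @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class PredictionRecord:
    """Per-threshold PC probabilities and their PCMT average for one sample."""

    sample_id: str
    per_threshold_probs: dict[float, float]
    pcmt_prob: float
    per_threshold_n_selected: dict[float, int]
    fallback_thresholds: tuple[float, ...] = ()


def fit_l1_logistic(
    train_matrix: np.ndarray,
    train_labels: np.ndarray,
    regularization_strength: float = 1.0,
) -> FittedLinearModel:
    """Fit a sparse logistic regression (L1 penalty, liblinear).

    ``regularization_strength`` is the inverse penalty weight C; the default
    1.0 is the conventional library default. Deterministic for fixed inputs.
    """
    train_matrix = np.asarray(train_matrix, dtype=float)
    train_labels = np.asarray(train_labels, dtype=int)
    classes = np.unique(train_labels)
    if len(classes) < 2:
        raise SingleClassError(
            f"training labels are all {classes[0]}; cannot fit a classifier"
        )
    if train_matrix.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    clf = LogisticRegression(
        l1_ratio=1.0,  # pure lasso penalty
        C=regularization_strength,
        solver="liblinear",
        tol=1e-4,
        max_iter=1000,
        random_state=0,  # liblinear shuffles internally; pin for determinism
    )
    clf.fit(train_matrix, train_labels)
    # liblinear orders classes ascending, so index 1 is the poor class
    return FittedLinearModel(
        coefficients=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        training_sample_count=train_matrix.shape[0],
    )


def _pc_from_selection(
    train: ExpressionDataset,
    selection: SelectionResult,
    regularization_strength: float,
) -> tuple[Optional[FittedLinearModel], bool]:
    """Fit the PC on a selection; (None, True) signals the degenerate fallback.

    Fallback condition: the selected subset is empty or single-class. The
    caller then predicts the poor-class prevalence of the full training set.
    """
    if selection.is_empty:
        return None, True
    labels = train.labels[selection.selected_indices]
    if len(np.unique(labels)) < 2:
        return None, True
    model = fit_l1_logistic(
        train.matrix[selection.selected_indices], labels, regularization_strength
    )
    return model, False


def personalized_probability(
    train: ExpressionDataset,
    test_vector: np.ndarray,
    threshold: float,
    mode: str = "signed",
    regularization_strength: float = 1.0,
    pcc: Optional[np.ndarray] = None,
) -> tuple[float, SelectionResult, bool]:
    """Poor-class probability for one test sample from a single PC.

    Returns ``(probability, selection, fallback)``. ``pcc`` may carry a
    precomputed correlation profile to avoid recomputation across thresholds.
    Degenerate selections fall back to the training poor-class prevalence.
    """
    if pcc is None:
        pcc = pearson_profile(test_vector, train.matrix)
    selection = select_training_subset(pcc, threshold, mode)
    model, fallback = _pc_from_selection(train, selection, regularization_strength)
    if fallback:
        return train.poor_prevalence, selection, True
    prob = float(model.predict_proba(np.asarray(test_vector, dtype=float))[0])
    return prob, selection, False


def pcmt_predict(
    train: ExpressionDataset,
    test_vector: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    mode: str = "signed",
    sample_id: str = "",
    regularization_strength: float = 1.0,
) -> PredictionRecord:
    """PCMT prediction for one test sample.

    One PC per threshold is trained on that threshold's selection; the PCMT
    probability is the unweighted arithmetic mean of the per-threshold
    probabilities. Always terminates with a valid record: degenerate
    selections contribute the documented fallback probability.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    pcc = pearson_profile(test_vector, train.matrix)
    probs: dict[float, float] = {}
    n_sel: dict[float, int] = {}
    fallbacks: list[float] = []
    for t in thresholds:
        p, sel, fb = personalized_probability(
            train, test_vector, t, mode, regularization_strength, pcc=pcc
        )
        probs[t] = p
        n_sel[t] = sel.n_selected
        if fb:
            fallbacks.append(t)
    return PredictionRecord(
        sample_id=sample_id,
        per_threshold_probs=probs,
        pcmt_prob=float(np.mean(list(probs.values()))),
        per_threshold_n_selected=n_sel,
        fallback_thresholds=tuple(fallbacks),
    )


class PCMTClassifier:
    """Personalized classifier with multiple thresholds, estimator-style.

    ``fit`` only stores the cohort: the actual models are trained lazily, per
    test sample. ``predict_records`` exposes the per-threshold probabilities
    so single-PC performance can be read off the same computation.
    """

    def __init__(
        self,
        thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
        mode: str = "signed",
        regularization_strength: float = 1.0,
    ):
        self.thresholds = list(thresholds)
        self.mode = mode
        self.regularization_strength = regularization_strength
        self.train_: Optional[ExpressionDataset] = None

    def fit(self, train: ExpressionDataset) -> "PCMTClassifier":
        self.train_ = train
        return self

    def predict_records(self, test: ExpressionDataset) -> list[PredictionRecord]:
        if self.train_ is None:
            raise RuntimeError("fit must be called before predict")
        train = self.train_
        pcc_matrix = pearson_cross_profile(test.matrix, train.matrix)
        records = []
        for i in range(test.n_samples):
            pcc = pcc_matrix[i]
            probs: dict[float, float] = {}
            n_sel: dict[float, int] = {}
            fallbacks: list[float] = []
            for t in self.thresholds:
                p, sel, fb = personalized_probability(
                    train,
                    test.matrix[i],
                    t,
                    self.mode,
                    self.regularization_strength,
                    pcc=pcc,
                )
                probs[t] = p
                n_sel[t] = sel.n_selected
                if fb:
                    fallbacks.append(t)
            records.append(
                PredictionRecord(
                    sample_id=str(test.sample_ids[i]),
                    per_threshold_probs=probs,
                    pcmt_prob=float(np.mean(list(probs.values()))),
                    per_threshold_n_selected=n_sel,
                    fallback_thresholds=tuple(fallbacks),
                )
            )
        return records

    def predict_proba(self, test: ExpressionDataset) -> np.ndarray:
        """PCMT poor-class probability per test sample."""
        return np.array([r.pcmt_prob for r in self.predict_records(test)])


class PooledLogistic:
    """Comparator: one sparse logistic model trained on the whole cohort."""

    def __init__(self, regularization_strength: float = 1.0):
        self.regularization_strength = regularization_strength
        self.model_: Optional[FittedLinearModel] = None

    def fit(self, train: ExpressionDataset) -> "PooledLogistic":
        self.model_ = fit_l1_logistic(
            train.matrix, train.labels, self.regularization_strength
        )
        return self

    def predict_proba(self, test: ExpressionDataset) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("fit must be called before predict")
        return self.model_.predict_proba(test.matrix)

    def feature_importances(self) -> np.ndarray:
        """|coefficient| per gene."""
        if self.model_ is None:
            raise RuntimeError("fit must be called before feature_importances")
        return np.abs(self.model_.coefficients)


class PooledRandomForest:
    """Comparator: random forest on the whole cohort (100 trees, seeded)."""

    def __init__(self, seed: int = 0, n_estimators: int = 100):
        self.seed = seed
        self.n_estimators = n_estimators
        self.model_: Optional[RandomForestClassifier] = None

    def fit(self, train: ExpressionDataset) -> "PooledRandomForest":
        classes = np.unique(train.labels)
        if len(classes) < 2:
            raise SingleClassError("random forest needs both outcome classes")
        rf = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.seed
        )
        rf.fit(train.matrix, train.labels)
        self.model_ = rf
        return self

    def predict_proba(self, test: ExpressionDataset) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("fit must be called before predict")
        poor_col = int(np.flatnonzero(self.model_.classes_ == 1)[0])
        return self.model_.predict_proba(test.matrix)[:, poor_col]

    def feature_importances(self) -> np.ndarray:
        """Impurity-based importance per gene."""
        if self.model_ is None:
            raise RuntimeError("fit must be called before feature_importances")
        return self.model_.feature_importances_.copy()
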