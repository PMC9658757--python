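"""Cross-validation harness: repeated stratified 5-fold CV, leave-one-study-out
CV, leave-one-out CV, ROC-AUC scoring, paired significance tests and
subtype-restricted AUC extraction.

All models inside one scheme run see identical train/test partitions, so AUC
vectors are paired and a paired t-test across folds (or held-out studies) is
valid. The poor/metastatic class is the positive class for every AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "auc",
    "paired_t_test",
    "run_five_fold",
    "run_loso",
    "run_loocv",
    "subtype_auc",
    "run_subtype_specific_loocv",
]


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve; the positive class is label 1.

    Equals the Mann–Whitney probability that a random positive outscores a
    random negative, with ties counted 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))


def paired_t_test(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Two-sided paired t-test p-value between matched score vectors.

    Element i of both vectors must come from the same fold/study. When the
    paired differences have zero variance the statistic is degenerate: the
    p-value is 1.0 for an identically-zero mean difference and NaN (the
    degenerate flag) otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    diff = a - b
    scale = max(1.0, float(np.abs(diff).max()))
    if np.ptp(diff) <= 1e-10 * scale:  # constant difference up to float noise
        return 1.0 if abs(diff.mean()) <= 1e-10 * scale else float("nan")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class EvaluationReport:
    """Result of one cross-validation scheme run over a set of models.

    ``auc_scores`` maps (model, unit) -> AUC where unit is a fold index
    ("rep0_fold1"), a study id, or "all"; undefined AUCs (single-class test
    units) are stored as NaN. ``predictions`` keeps per-sample probabilities
    for schemes that produce them (LOOCV) so subtype slices can be scored
    afterwards.
    """

    scheme: str
    auc_scores: dict[tuple[str, str], float]
    predictions: dict[str, np.ndarray] = field(default_factory=dict)
    sample_ids: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    fold_assignments: Optional[dict[str, np.ndarray]] = None
    seed: Optional[int] = None

    def auc_vector(self, model: str) -> np.ndarray:
        """AUCs for one model in unit order, NaNs dropped consistently."""
        units = self.units()
        return np.array([self.auc_scores[(model, u)] for u in units])

    def units(self) -> list[str]:
        seen: list[str] = []
        for _, u in self.auc_scores:
            if u not in seen:
                seen.append(u)
        return seen

    def models(self) -> list[str]:
        seen: list[str] = []
        for m, _ in self.auc_scores:
            if m not in seen:
                seen.append(m)
        return seen

    def pairwise_p(self) -> dict[tuple[str, str], float]:
        """Paired t-test p-values over shared valid units, all model pairs."""
        out: dict[tuple[str, str], float] = {}
        models = self.models()
        for i, ma in enumerate(models):
            for mb in models[i + 1 :]:
                va, vb = self.auc_vector(ma), self.auc_vector(mb)
                ok = np.isfinite(va) & np.isfinite(vb)
                if ok.sum() >= 2:
                    out[(ma, mb)] = paired_t_test(va[ok], vb[ok])
                else:
                    out[(ma, mb)] = float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "unit": u, "auc": v} for (m, u), v in self.auc_scores.items()
        ]
        return pd.DataFrame(rows)


def _score_split(
    d: ExpressionDataset,
    models: Mapping[str, object],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    unit: str,
    report: EvaluationReport,
) -> None:
    train = d.subset_samples(train_idx)
    test = d.subset_samples(test_idx)
    y = test.labels
    for name, model in models.items():
        probs = np.asarray(model.fit(train).predict_proba(test), dtype=float)
        if len(np.unique(y)) < 2:
            logger.warning("unit %s holds a single class; AUC undefined", unit)
            report.auc_scores[(name, unit)] = float("nan")
        else:
            report.auc_scores[(name, unit)] = auc(y, probs)


def run_five_fold(
    d: ExpressionDataset,
    models: Mapping[str, object],
    n_repeats: int = 8,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified 5-fold CV repeated ``n_repeats`` times.

    Every model sees the same folds within a repeat, giving 5 x n_repeats
    paired AUC scores per model (40 at the default eight repeats).
    """
    if d.n_samples < 10:
        raise ValueError("need at least 10 samples for stratified 5-fold CV")
    report = EvaluationReport(scheme="five_fold_repeated", auc_scores={}, seed=seed,
                              fold_assignments={})
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed + rep)
        for fold, (train_idx, test_idx) in enumerate(
            skf.split(d.matrix, d.labels)
        ):
            unit = f"rep{rep}_fold{fold}"
            report.fold_assignments[unit] = test_idx
            _score_split(d, models, train_idx, test_idx, unit, report)
    return report


def run_loso(d: ExpressionDataset, models: Mapping[str, object]) -> EvaluationReport:
    """Leave-one-study-out CV: one AUC per (model, held-out study).

    A held-out study containing a single outcome class gets a NaN AUC and is
    excluded from paired tests.
    """
    if d.studies is None:
        raise ValueError("dataset has no study annotation")
    studies = pd.unique(d.studies)
    if len(studies) < 2:
        raise ValueError("leave-one-study-out needs at least 2 studies")
    report = EvaluationReport(scheme="loso", auc_scores={}, fold_assignments={})
    for study in studies:
        test_idx = np.flatnonzero(d.studies == study)
        train_idx = np.flatnonzero(d.studies != study)
        report.fold_assignments[str(study)] = test_idx
        _score_split(d, models, train_idx, test_idx, str(study), report)
    return report


def run_loocv(d: ExpressionDataset, models: Mapping[str, object]) -> EvaluationReport:
    """Leave-one-out CV: per-sample probabilities and one pooled AUC per model."""
    if d.n_samples < 4:
        raise ValueError("need at least 4 samples for LOOCV")
    report = EvaluationReport(
        scheme="loocv",
        auc_scores={},
        sample_ids=d.sample_ids.copy(),
        labels=d.labels.copy(),
    )
    all_idx = np.arange(d.n_samples)
    preds = {name: np.empty(d.n_samples) for name in models}
    for i in range(d.n_samples):
        train = d.subset_samples(np.delete(all_idx, i))
        test = d.subset_samples(np.array([i]))
        for name, model in models.items():
            preds[name][i] = float(
                np.asarray(model.fit(train).predict_proba(test), dtype=float)[0]
            )
    for name, p in preds.items():
        report.predictions[name] = p
        report.auc_scores[(name, "all")] = auc(d.labels, p)
    return report


def subtype_auc(
    report: EvaluationReport, subtypes: np.ndarray
) -> dict[str, dict[str, float]]:
    """Per-subtype AUC from pooled LOOCV probabilities.

    For each model, the stored per-sample probabilities are sliced by subtype
    and scored; a single-class slice yields NaN (undefined).
    """
    if report.scheme != "loocv" or not report.predictions:
        raise ValueError("subtype_auc needs a LOOCV report with stored predictions")
    subtypes = np.asarray(subtypes, dtype=object)
    if len(subtypes) != len(report.labels):
        raise ValueError("subtype annotation length mismatch")
    out: dict[str, dict[str, float]] = {}
    for name, probs in report.predictions.items():
        per = {}
        for st in pd.unique(subtypes):
            mask = subtypes == st
            y = report.labels[mask]
            if len(np.unique(y)) < 2:
                logger.warning("subtype %s holds a single class; AUC undefined", st)
                per[str(st)] = float("nan")
            else:
                per[str(st)] = auc(y, probs[mask])
        out[name] = per
    return out


def run_subtype_specific_loocv(
    d: ExpressionDataset, model_factory, min_size: int = 4
) -> dict[str, float]:
    """Subtype-internal LOOCV AUC for base models.

    One model family is trained and evaluated entirely within each subtype
    (the comparator protocol for subtype-specific classifiers); subtypes too
    small or single-class come back NaN.
    """
    if d.subtypes is None:
        raise ValueError("dataset has no subtype annotation")
    out: dict[str, float] = {}
    for st in pd.unique(d.subtypes):
        idx = np.flatnonzero(d.subtypes == st)
        sub = d.subset_samples(idx)
        if sub.n_samples < min_size or len(np.unique(sub.labels)) < 2:
            out[str(st)] = float("nan")
            continue
        rep = run_loocv(sub, {"m": model_factory()})
        out[str(st)] = rep.auc_scores[("m", "all")]
    return out
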