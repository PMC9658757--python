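"""Correlation-based selection of personalized training subsets.

For one test sample, similarity to every training sample is the Pearson
correlation coefficient (PCC) between the two full gene-expression vectors.
The personalized training subset keeps the training samples whose |PCC|
strictly exceeds a threshold (signed mode: both strongly positively and
strongly negatively correlated patients) or whose PCC strictly exceeds it
(positive-only mode, the ablation).

Selection is a pure function: an empty or single-class subset is reported
as-is, and the classifier layer owns the fallback behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionResult",
    "pearson_profile",
    "select_training_subset",
    "threshold_grid",
    "DEFAULT_THRESHOLDS",
]

MODES = ("signed", "positive_only")


@dataclass(frozen=True)
class SelectionResult:
    """Training subset chosen for one test sample at one threshold."""

    selected_indices: np.ndarray  # positions into the training set, original order
    pcc_values: np.ndarray  # PCC of each selected sample
    n_positive: int  # selected with PCC > 0
    n_negative: int  # selected with PCC < 0
    threshold: float
    mode: str

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    @property
    def is_empty(self) -> bool:
        return self.n_selected == 0


def pearson_profile(test_vector: np.ndarray, train_matrix: np.ndarray) -> np.ndarray:
    """PCC between one test profile and every training profile.

    Correlation is taken across genes, i.e. each sample's full expression
    vector is one observation series. Constant profiles have undefined
    correlation and are rejected.
    """
    test_vector = np.asarray(test_vector, dtype=float).ravel()
    train_matrix = np.atleast_2d(np.asarray(train_matrix, dtype=float))
    if train_matrix.shape[1] != test_vector.size:
        raise ValueError("gene dimensions of test vector and training matrix differ")
    if test_vector.size < 2:
        raise ValueError("need at least 2 genes to compute a correlation")

    tc = test_vector - test_vector.mean()
    t_norm = np.sqrt(np.sum(tc**2))
    if t_norm == 0:
        raise ValueError("test sample has constant expression; PCC undefined")
    xc = train_matrix - train_matrix.mean(axis=1, keepdims=True)
    x_norm = np.sqrt(np.sum(xc**2, axis=1))
    if (x_norm == 0).any():
        bad = int(np.flatnonzero(x_norm == 0)[0])
        raise ValueError(f"training sample at index {bad} has constant expression; PCC undefined")
    return np.clip(xc @ tc / (x_norm * t_norm), -1.0, 1.0)


def pearson_cross_profile(test_matrix: np.ndarray, train_matrix: np.ndarray) -> np.ndarray:
    """All-pairs PCC matrix (n_test x n_train); vectorized pearson_profile."""
    test_matrix = np.atleast_2d(np.asarray(test_matrix, dtype=float))
    train_matrix = np.atleast_2d(np.asarray(train_matrix, dtype=float))
    tc = test_matrix - test_matrix.mean(axis=1, keepdims=True)
    xc = train_matrix - train_matrix.mean(axis=1, keepdims=True)
    t_norm = np.sqrt(np.sum(tc**2, axis=1))
    x_norm = np.sqrt(np.sum(xc**2, axis=1))
    for name, norms in (("test", t_norm), ("training", x_norm)):
        if (norms == 0).any():
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"{name} sample at index {bad} has constant expression; PCC undefined")
    return np.clip((tc @ xc.T) / np.outer(t_norm, x_norm), -1.0, 1.0)


def select_training_subset(
    pcc: np.ndarray, threshold: float, mode: str = "signed"
) -> SelectionResult:
    """Select training samples whose correlation strictly exceeds the threshold.

    signed mode keeps samples with ``|PCC| > threshold``; positive_only keeps
    samples with ``PCC > threshold``. Training order is preserved; samples
    exactly at the threshold are excluded (strict inequality).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    pcc = np.asarray(pcc, dtype=float)
    if mode == "signed":
        mask = np.abs(pcc) > threshold
    else:
        mask = pcc > threshold
    idx = np.flatnonzero(mask)
    vals = pcc[idx]
    return SelectionResult(
        selected_indices=idx,
        pcc_values=vals,
        n_positive=int(np.sum(vals > 0)),
        n_negative=int(np.sum(vals < 0)),
        threshold=float(threshold),
        mode=mode,
    )


def threshold_grid(start: float, stop: float, step: float) -> list[float]:
    """Inclusive arithmetic sequence of PCC thresholds."""
    if step <= 0:
        raise ValueError("step must be positive")
    if start > stop:
        raise ValueError("start must not exceed stop")
    n = int(round((stop - start) / step))
    grid = [start + k * step for k in range(n + 1)]
    # guard against float drift at the inclusive endpoint
    if grid[-1] > stop + 1e-12:
        grid.pop()
    return [round(t, 12) for t in grid]


#: Threshold grid covering subtype population sizes in a ~1600-sample cohort.
DEFAULT_THRESHOLDS = threshold_grid(0.15, 0.275, 0.025)
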