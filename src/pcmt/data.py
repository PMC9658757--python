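"""Expression-cohort container, delimited-text I/O and cross-dataset preparation.

The universal in-memory object is :class:`ExpressionDataset`: a dense
samples x genes matrix of normalized expression values with aligned binary
outcome labels and optional subtype / study-of-origin annotations.

On-disk layout (all tab-delimited text):

* matrix file — header row of gene ids, first column of sample ids,
  one row per sample;
* labels file — two columns ``sample_id``, ``label`` with labels in {0, 1}
  (1 = poor / metastatic outcome);
* annotations file (optional) — ``sample_id`` plus any of ``subtype``,
  ``study``.

Cross-dataset preparation follows the usual microarray/RNA-seq integration
recipe: restrict both cohorts to their common genes, optionally mean-center
each gene, then quantile-normalize all samples of both cohorts against a
single mean-quantile reference so the two sources share one distribution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "OutcomeLabel",
    "DatasetError",
    "load_dataset",
    "write_dataset",
    "intersect_genes",
    "mean_center",
    "quantile_normalize_joint",
    "label_from_pfi",
]


class DatasetError(ValueError):
    """Raised when a dataset violates the container contract at load/build time."""


class OutcomeLabel(enum.Enum):
    """Three-state prognostic outcome derived from follow-up attributes."""

    GOOD = "good"
    POOR = "poor"
    UNDECIDED = "undecided"


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with aligned per-sample annotations.

    Parameters
    ----------
    matrix
        Real-valued array of shape ``(n_samples, n_genes)``; no missing values.
    gene_ids, sample_ids
        Unique ordered identifiers for columns and rows respectively.
    labels
        Binary outcome per sample; 1 = poor/metastatic (the positive class).
    subtypes, studies
        Optional categorical annotations, one entry per sample.
    attrs
        Free-form metadata (e.g. the generating oracle of a synthetic cohort).
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray
    subtypes: Optional[np.ndarray] = None
    studies: Optional[np.ndarray] = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise DatasetError("expression matrix must be 2-dimensional")
        n, g = self.matrix.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise DatasetError(
                f"row mismatch: matrix has {n} samples, "
                f"{len(self.sample_ids)} sample ids, {len(self.labels)} labels"
            )
        if len(self.gene_ids) != g:
            raise DatasetError(
                f"column mismatch: matrix has {g} genes but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != g:
            raise DatasetError("duplicate gene ids")
        if len(set(self.sample_ids)) != n:
            raise DatasetError("duplicate sample ids")
        if not np.isfinite(self.matrix).all():
            bad = np.argwhere(~np.isfinite(self.matrix))[0]
            raise DatasetError(
                f"missing/non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )
        if not np.isin(self.labels, [0, 1]).all():
            raise DatasetError("labels must be binary 0/1 (1 = poor outcome)")
        self.labels = self.labels.astype(int)
        for name in ("subtypes", "studies"):
            ann = getattr(self, name)
            if ann is not None:
                ann = np.asarray(ann, dtype=object)
                if len(ann) != n:
                    raise DatasetError(f"{name} annotation length != n_samples")
                setattr(self, name, ann)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def poor_prevalence(self) -> float:
        """Fraction of samples with the poor (positive) outcome."""
        return float(self.labels.mean())

    def subset_samples(self, index: np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to the given sample positions (order kept)."""
        index = np.asarray(index)
        return ExpressionDataset(
            matrix=self.matrix[index],
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids[index],
            labels=self.labels[index],
            subtypes=None if self.subtypes is None else self.subtypes[index],
            studies=None if self.studies is None else self.studies[index],
            attrs=dict(self.attrs),
        )

    def subset_genes(self, gene_index: np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to the given gene positions (order kept)."""
        gene_index = np.asarray(gene_index)
        return replace(
            self,
            matrix=self.matrix[:, gene_index],
            gene_ids=self.gene_ids[gene_index],
            attrs=dict(self.attrs),
        )

    def with_matrix(self, matrix: np.ndarray) -> "ExpressionDataset":
        return replace(self, matrix=np.asarray(matrix, dtype=float), attrs=dict(self.attrs))


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def load_dataset(
    matrix_path: Union[str, Path],
    labels_path: Union[str, Path],
    annotations_path: Optional[Union[str, Path]] = None,
) -> ExpressionDataset:
    """Load an :class:`ExpressionDataset` from tab-delimited text files.

    Sample order follows the matrix file. Every matrix sample must appear in
    the labels file; the annotations file (if given) may carry ``subtype``
    and/or ``study`` columns.
    """
    mat = _read_table(matrix_path)
    # locate non-numeric cells before coercion so the error can name them
    numeric = mat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~mat.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise DatasetError(
            f"non-numeric cell at sample {mat.index[r]!r}, gene {mat.columns[c]!r} "
            f"in {matrix_path}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise DatasetError(
            f"empty cell at sample {mat.index[r]!r}, gene {mat.columns[c]!r} in {matrix_path}"
        )

    labels_df = _read_table(labels_path)
    missing = [s for s in mat.index if s not in labels_df.index]
    if missing:
        raise DatasetError(f"sample id {missing[0]!r} has no label in {labels_path}")
    labels = labels_df.iloc[:, 0].reindex(mat.index).to_numpy()

    subtypes = studies = None
    if annotations_path is not None:
        ann = _read_table(annotations_path)
        missing = [s for s in mat.index if s not in ann.index]
        if missing:
            raise DatasetError(
                f"sample id {missing[0]!r} has no annotation in {annotations_path}"
            )
        ann = ann.reindex(mat.index)
        if "subtype" in ann.columns:
            subtypes = ann["subtype"].to_numpy()
        if "study" in ann.columns:
            studies = ann["study"].to_numpy()

    return ExpressionDataset(
        matrix=numeric.to_numpy(dtype=float),
        gene_ids=mat.columns.to_numpy(dtype=object),
        sample_ids=mat.index.to_numpy(dtype=object),
        labels=labels,
        subtypes=subtypes,
        studies=studies,
    )


def write_dataset(
    d: ExpressionDataset,
    matrix_path: Union[str, Path],
    labels_path: Union[str, Path],
    annotations_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write a dataset back to the tab-delimited layout read by :func:`load_dataset`.

    The matrix is written with ``repr`` round-trip precision so that
    load(write(d)) reproduces the numbers bit-exactly.
    """
    mdf = pd.DataFrame(d.matrix, index=d.sample_ids, columns=d.gene_ids)
    mdf.index.name = "sample_id"
    mdf.to_csv(matrix_path, sep="\t", float_format=None)
    ldf = pd.DataFrame({"label": d.labels}, index=d.sample_ids)
    ldf.index.name = "sample_id"
    ldf.to_csv(labels_path, sep="\t")
    if annotations_path is not None:
        cols = {}
        if d.subtypes is not None:
            cols["subtype"] = d.subtypes
        if d.studies is not None:
            cols["study"] = d.studies
        adf = pd.DataFrame(cols, index=d.sample_ids)
        adf.index.name = "sample_id"
        adf.to_csv(annotations_path, sep="\t")


def intersect_genes(
    a: ExpressionDataset, b: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both cohorts to their common genes, in a's gene order."""
    common = set(a.gene_ids) & set(b.gene_ids)
    if not common:
        raise DatasetError("datasets share no genes")
    keep_a = np.array([i for i, g in enumerate(a.gene_ids) if g in common])
    order = a.gene_ids[keep_a]
    pos_b = {g: i for i, g in enumerate(b.gene_ids)}
    keep_b = np.array([pos_b[g] for g in order])
    return a.subset_genes(keep_a), b.subset_genes(keep_b)


def mean_center(d: ExpressionDataset) -> ExpressionDataset:
    """Center each gene to mean zero across samples (idempotent)."""
    return d.with_matrix(d.matrix - d.matrix.mean(axis=0, keepdims=True))


def _quantile_normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize each row against the mean-quantile reference.

    Reference distribution: the mean across rows of row-sorted values. Tied
    values within a row receive the mean of the reference values at their
    tied ranks (the limma convention).
    """
    order = np.argsort(matrix, axis=1, kind="stable")
    reference = np.take_along_axis(matrix, order, axis=1).mean(axis=0)
    out = np.empty_like(matrix, dtype=float)
    n = matrix.shape[1]
    for i, row in enumerate(matrix):
        idx = order[i]
        vals = row[idx]
        j = 0
        while j < n:
            k = j
            while k + 1 < n and vals[k + 1] == vals[j]:
                k += 1
            out[i, idx[j : k + 1]] = reference[j : k + 1].mean()
            j = k + 1
    return out


def quantile_normalize_joint(
    a: ExpressionDataset, b: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Quantile-normalize all samples of both cohorts to one shared reference.

    The reference is the mean quantile distribution over the pooled samples of
    ``a`` and ``b``; afterwards every sample's sorted value vector is identical,
    so the two sources share the same marginal distribution.
    """
    if len(a.gene_ids) != len(b.gene_ids) or (a.gene_ids != b.gene_ids).any():
        raise DatasetError("gene lists differ; call intersect_genes first")
    pooled = np.vstack([a.matrix, b.matrix])
    normed = _quantile_normalize_rows(pooled)
    return a.with_matrix(normed[: a.n_samples]), b.with_matrix(normed[a.n_samples :])


def label_from_pfi(pfi_time_years: float, event: int) -> OutcomeLabel:
    """Outcome label from progression-free interval and event indicator.

    good if the patient was progression-free beyond 5 years; poor if a
    progression event occurred within (or at) 5 years; undecided otherwise
    (censored before 5 years).
    """
    if pfi_time_years < 0:
        raise ValueError("pfi_time_years must be nonnegative")
    if event not in (0, 1):
        raise ValueError("event must be 0 or 1")
    if pfi_time_years > 5:
        return OutcomeLabel.GOOD
    if event == 1:
        return OutcomeLabel.POOR
    return OutcomeLabel.UNDECIDED
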