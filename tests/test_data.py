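"""Dataset container, TSV round-trips and cross-dataset preparation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcmt.data import (
    DatasetError,
    ExpressionDataset,
    OutcomeLabel,
    intersect_genes,
    label_from_pfi,
    load_dataset,
    mean_center,
    quantile_normalize_joint,
    write_dataset,
)


def _write_files(tmp_path, matrix_text, labels_text, ann_text=None):
    mp = tmp_path / "m.tsv"
    lp = tmp_path / "l.tsv"
    mp.write_text(matrix_text)
    lp.write_text(labels_text)
    ap = None
    if ann_text is not None:
        ap = tmp_path / "a.tsv"
        ap.write_text(ann_text)
    return mp, lp, ap


MATRIX_3x2 = "sample_id\tgA\tgB\ns1\t1.0\t2.0\ns2\t3.0\t4.0\ns3\t5.0\t6.0\n"
LABELS_3 = "sample_id\tlabel\ns1\t0\ns2\t1\ns3\t0\n"


class TestLoadDataset:
    def test_basic_load(self, tmp_path):
        mp, lp, _ = _write_files(tmp_path, MATRIX_3x2, LABELS_3)
        d = load_dataset(mp, lp)
        assert d.n_samples == 3 and d.n_genes == 2
        assert list(d.labels) == [0, 1, 0]
        np.testing.assert_array_equal(d.matrix, [[1, 2], [3, 4], [5, 6]])

    def test_missing_label_names_offender(self, tmp_path):
        mp, lp, _ = _write_files(
            tmp_path, MATRIX_3x2, "sample_id\tlabel\ns1\t0\ns3\t0\n"
        )
        with pytest.raises(DatasetError, match="s2"):
            load_dataset(mp, lp)

    def test_empty_cell_positions_error(self, tmp_path):
        bad = MATRIX_3x2.replace("3.0\t4.0", "3.0\t")
        mp, lp, _ = _write_files(tmp_path, bad, LABELS_3)
        with pytest.raises(DatasetError, match="s2.*gB"):
            load_dataset(mp, lp)

    def test_non_numeric_cell_positions_error(self, tmp_path):
        bad = MATRIX_3x2.replace("4.0", "oops")
        mp, lp, _ = _write_files(tmp_path, bad, LABELS_3)
        with pytest.raises(DatasetError, match="s2.*gB"):
            load_dataset(mp, lp)

    def test_annotations_loaded(self, tmp_path):
        ann = "sample_id\tsubtype\tstudy\ns1\tA\tX\ns2\tB\tX\ns3\tA\tY\n"
        mp, lp, ap = _write_files(tmp_path, MATRIX_3x2, LABELS_3, ann)
        d = load_dataset(mp, lp, ap)
        assert list(d.subtypes) == ["A", "B", "A"]
        assert list(d.studies) == ["X", "X", "Y"]

    def test_roundtrip_bit_exact(self, tmp_path, tiny_dataset):
        write_dataset(
            tiny_dataset, tmp_path / "m.tsv", tmp_path / "l.tsv", tmp_path / "a.tsv"
        )
        d2 = load_dataset(tmp_path / "m.tsv", tmp_path / "l.tsv", tmp_path / "a.tsv")
        np.testing.assert_array_equal(d2.matrix, tiny_dataset.matrix)
        np.testing.assert_array_equal(d2.labels, tiny_dataset.labels)
        assert list(d2.subtypes) == list(tiny_dataset.subtypes)


class TestContainerContract:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(DatasetError, match="duplicate gene"):
            ExpressionDataset(
                matrix=np.zeros((2, 2)),
                gene_ids=["g", "g"],
                sample_ids=["a", "b"],
                labels=[0, 1],
            )

    def test_nan_rejected_with_position(self):
        m = np.zeros((2, 2))
        m[1, 0] = np.nan
        with pytest.raises(DatasetError, match="'b'.*'g0'"):
            ExpressionDataset(
                matrix=m, gene_ids=["g0", "g1"], sample_ids=["a", "b"], labels=[0, 1]
            )

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(DatasetError, match="binary"):
            ExpressionDataset(
                matrix=np.zeros((2, 2)),
                gene_ids=["g0", "g1"],
                sample_ids=["a", "b"],
                labels=[0, 2],
            )


class TestIntersectGenes:
    def _ds(self, genes):
        n = 3
        return ExpressionDataset(
            matrix=np.arange(n * len(genes), dtype=float).reshape(n, len(genes)),
            gene_ids=genes,
            sample_ids=[f"s{i}" for i in range(n)],
            labels=[0, 1, 0],
        )

    def test_partial_overlap(self):
        a, b = intersect_genes(self._ds(["A", "B", "C"]), self._ds(["B", "C", "D"]))
        assert list(a.gene_ids) == ["B", "C"] and list(b.gene_ids) == ["B", "C"]

    def test_identical_lists_unchanged(self):
        d = self._ds(["A", "B"])
        a, b = intersect_genes(d, self._ds(["A", "B"]))
        np.testing.assert_array_equal(a.matrix, d.matrix)
        np.testing.assert_array_equal(b.matrix, d.matrix)

    def test_disjoint_errors(self):
        with pytest.raises(DatasetError):
            intersect_genes(self._ds(["A"]), self._ds(["B"]))


class TestMeanCenter:
    def test_closed_form(self):
        d = ExpressionDataset(
            matrix=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
            gene_ids=["g0", "g1"],
            sample_ids=["a", "b", "c"],
            labels=[0, 1, 0],
        )
        c = mean_center(d)
        np.testing.assert_allclose(c.matrix[:, 0], [-1, 0, 1])
        np.testing.assert_allclose(c.matrix[:, 1], [0, 0, 0])

    def test_idempotent(self, tiny_dataset):
        once = mean_center(tiny_dataset)
        twice = mean_center(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-14)


def _qn_oracle(matrix):
    """Brute-force quantile normalization: per-row average rank -> mean of
    reference values at the occupied tied ranks."""
    matrix = np.asarray(matrix, dtype=float)
    n_rows, n_cols = matrix.shape
    ref = np.sort(matrix, axis=1).mean(axis=0)
    out = np.empty_like(matrix)
    for i in range(n_rows):
        row = matrix[i]
        for j in range(n_cols):
            ranks = np.flatnonzero(np.sort(row) == row[j])
            out[i, j] = ref[ranks].mean()
    return out


class TestQuantileNormalizeJoint:
    def _pair(self, ma, mb):
        genes = [f"g{i}" for i in range(np.asarray(ma).shape[1])]

        def ds(m, prefix):
            m = np.asarray(m, dtype=float)
            return ExpressionDataset(
                matrix=m,
                gene_ids=genes,
                sample_ids=[f"{prefix}{i}" for i in range(m.shape[0])],
                labels=[i % 2 for i in range(m.shape[0])],
            )

        return ds(ma, "a"), ds(mb, "b")

    def test_mean_quantile_reference(self):
        a, b = self._pair([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        qa, qb = quantile_normalize_joint(a, b)
        np.testing.assert_allclose(qa.matrix[0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(qb.matrix[0], [2.5, 3.5, 4.5])

    def test_identical_samples_unchanged(self):
        a, b = self._pair([[3.0, 1.0, 2.0]], [[3.0, 1.0, 2.0]])
        qa, qb = quantile_normalize_joint(a, b)
        np.testing.assert_allclose(qa.matrix, a.matrix)
        np.testing.assert_allclose(qb.matrix, b.matrix)

    def test_matches_rank_average_oracle_with_ties(self):
        ma = [[1.0, 1.0, 2.0, 5.0], [0.0, 3.0, 3.0, 3.0]]
        mb = [[2.0, 2.0, 2.0, 2.0], [7.0, 1.0, 4.0, 4.0]]
        a, b = self._pair(ma, mb)
        qa, qb = quantile_normalize_joint(a, b)
        expected = _qn_oracle(np.vstack([ma, mb]))
        np.testing.assert_allclose(np.vstack([qa.matrix, qb.matrix]), expected)

    def test_sorted_values_identical_across_samples(self):
        rng = np.random.default_rng(0)
        a, b = self._pair(rng.normal(size=(4, 7)), rng.normal(size=(3, 7)) * 2 + 1)
        qa, qb = quantile_normalize_joint(a, b)
        pooled = np.vstack([qa.matrix, qb.matrix])
        ref = np.sort(pooled[0])
        for row in pooled[1:]:
            np.testing.assert_allclose(np.sort(row), ref)

    def test_differing_gene_lists_rejected(self, tiny_dataset):
        other = tiny_dataset.subset_genes(np.arange(3))
        with pytest.raises(DatasetError):
            quantile_normalize_joint(tiny_dataset, other)


class TestLabelFromPfi:
    @pytest.mark.parametrize(
        "time,event,expected",
        [
            (6.0, 0, OutcomeLabel.GOOD),
            (6.0, 1, OutcomeLabel.GOOD),
            (3.0, 1, OutcomeLabel.POOR),
            (5.0, 1, OutcomeLabel.POOR),  # boundary: exactly 5 years counts as poor
            (3.0, 0, OutcomeLabel.UNDECIDED),
            (0.0, 0, OutcomeLabel.UNDECIDED),
        ],
    )
    def test_rule(self, time, event, expected):
        assert label_from_pfi(time, event) is expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            label_from_pfi(-1.0, 1)

    @settings(max_examples=200, deadline=None)
    @given(
        t=st.floats(min_value=0, max_value=50, allow_nan=False),
        event=st.integers(min_value=0, max_value=1),
    )
    def test_partitions_the_plane(self, t, event):
        assert label_from_pfi(t, event) in set(OutcomeLabel)
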