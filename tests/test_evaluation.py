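"""Cross-validation schemes, AUC scoring and paired significance tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcmt.data import ExpressionDataset
from pcmt.evaluation import (
    auc,
    paired_t_test,
    run_five_fold,
    run_loocv,
    run_loso,
    run_subtype_specific_loocv,
    subtype_auc,
)
from pcmt.models import PCMTClassifier, PooledLogistic
from pcmt.simulate import GeneratorConfig, generate_cohort


def _pair_counting_auc(labels, scores):
    """O(n^2) Mann-Whitney oracle: P(random positive outscores random
    negative), ties counted 1/2."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class ConstantModel:
    """Uninformative comparator: the same score for every sample."""

    def __init__(self, value=0.5):
        self.value = value

    def fit(self, train):
        return self

    def predict_proba(self, test):
        return np.full(test.n_samples, self.value)


class StudyMemorizer:
    """Pathological comparator scoring constant within each study."""

    def fit(self, train):
        return self

    def predict_proba(self, test):
        codes = {s: i for i, s in enumerate(dict.fromkeys(test.studies))}
        return np.array([codes[s] / 10.0 for s in test.studies])


class TestAuc:
    def test_perfect_ranking(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_tie_convention(self):
        assert auc([0, 1], [0.5, 0.5]) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            labels = np.r_[0, 1, rng.integers(0, 2, 18)]
            scores = np.round(rng.random(20), 2)  # rounding induces ties
            assert auc(labels, scores) == pytest.approx(
                _pair_counting_auc(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_complement_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[0, 1, rng.integers(0, 2, 10)]
        scores = rng.random(12)  # continuous, ties have measure zero
        a = auc(labels, scores)
        assert auc(labels, -scores) == pytest.approx(1 - a, abs=1e-12)
        assert auc(labels, np.exp(3 * scores)) == pytest.approx(a, abs=1e-12)


class TestPairedTTest:
    def test_identical_vectors_degenerate_zero_diff(self):
        assert paired_t_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_constant_nonzero_difference_flagged(self):
        assert np.isnan(paired_t_test([0.7, 0.8, 0.9], [0.6, 0.7, 0.8]))

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(40), rng.random(40)
        diff = a - b
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        from scipy.stats import t as t_dist

        expected = 2 * t_dist.sf(abs(t), df=len(diff) - 1)
        assert paired_t_test(a, b) == pytest.approx(expected, abs=1e-10)


class TestFiveFold:
    def test_forty_scores_at_eight_repeats(self, small_cohort):
        rep = run_five_fold(small_cohort, {"lr": PooledLogistic()}, n_repeats=8, seed=1)
        assert len(rep.auc_vector("lr")) == 40

    def test_same_seed_same_folds(self, small_cohort):
        r1 = run_five_fold(small_cohort, {"c": ConstantModel()}, n_repeats=2, seed=9)
        r2 = run_five_fold(small_cohort, {"c": ConstantModel()}, n_repeats=2, seed=9)
        for unit in r1.fold_assignments:
            np.testing.assert_array_equal(
                r1.fold_assignments[unit], r2.fold_assignments[unit]
            )

    def test_constant_scores_give_half(self, small_cohort):
        rep = run_five_fold(small_cohort, {"c": ConstantModel()}, n_repeats=2, seed=0)
        np.testing.assert_allclose(rep.auc_vector("c"), 0.5)

    def test_folds_shared_across_models_and_stratified(self, small_cohort):
        rep = run_five_fold(
            small_cohort,
            {"a": ConstantModel(0.2), "b": ConstantModel(0.8)},
            n_repeats=1,
            seed=3,
        )
        # one assignment per unit serving all models, covering all samples once
        idx = np.concatenate(list(rep.fold_assignments.values()))
        assert sorted(idx) == list(range(small_cohort.n_samples))
        for test_idx in rep.fold_assignments.values():
            assert len(np.unique(small_cohort.labels[test_idx])) == 2


class TestLoso:
    def test_one_auc_per_study(self, small_cohort):
        rep = run_loso(small_cohort, {"lr": PooledLogistic()})
        assert len(rep.auc_vector("lr")) == len(set(small_cohort.studies))

    def test_twelve_study_cohort(self):
        d = generate_cohort(
            GeneratorConfig(n_samples=240, n_genes=40, n_studies=12, seed=5)
        )
        rep = run_loso(d, {"c": ConstantModel()})
        assert len(rep.auc_vector("c")) == 12

    def test_study_memorizer_scores_half(self, small_cohort):
        rep = run_loso(small_cohort, {"m": StudyMemorizer()})
        np.testing.assert_allclose(rep.auc_vector("m"), 0.5)

    def test_single_class_study_marked_undefined(self):
        rng = np.random.default_rng(4)
        d = ExpressionDataset(
            matrix=rng.normal(size=(12, 5)),
            gene_ids=[f"g{i}" for i in range(5)],
            sample_ids=[f"s{i}" for i in range(12)],
            labels=[0, 1] * 4 + [0, 0, 0, 0],
            studies=["a"] * 8 + ["b"] * 4,  # study b is all-good
        )
        rep = run_loso(d, {"c": ConstantModel()})
        assert np.isnan(rep.auc_scores[("c", "b")])
        assert np.isfinite(rep.auc_scores[("c", "a")])


class TestLoocv:
    def test_one_probability_per_sample(self, tiny_dataset):
        d = tiny_dataset
        rep = run_loocv(d, {"c": ConstantModel(), "lr": PooledLogistic()})
        assert rep.predictions["c"].shape == (d.n_samples,)
        assert rep.predictions["lr"].shape == (d.n_samples,)

    def test_strong_signal_reaches_high_auc(self, separable_cohort):
        rep = run_loocv(separable_cohort, {"pc": PCMTClassifier(thresholds=[0.2])})
        assert rep.auc_scores[("pc", "all")] > 0.9

    def test_label_shuffle_gives_chance_level(self, separable_cohort):
        """Permuting labels destroys the signal: pooled AUC near 0.5."""
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            d = ExpressionDataset(
                matrix=separable_cohort.matrix,
                gene_ids=separable_cohort.gene_ids,
                sample_ids=separable_cohort.sample_ids,
                labels=rng.permutation(separable_cohort.labels),
            )
            rep = run_loocv(d, {"lr": PooledLogistic()})
            aucs.append(rep.auc_scores[("lr", "all")])
        assert 0.3 <= np.median(aucs) <= 0.7


class TestSubtypeAuc:
    def test_slices_match_direct_recompute(self, small_cohort):
        rep = run_loocv(small_cohort, {"lr": PooledLogistic()})
        per = subtype_auc(rep, small_cohort.subtypes)["lr"]
        for st_name, value in per.items():
            mask = small_cohort.subtypes == st_name
            y = small_cohort.labels[mask]
            if len(np.unique(y)) < 2:
                assert np.isnan(value)
            else:
                assert value == pytest.approx(
                    auc(y, rep.predictions["lr"][mask]), abs=1e-12
                )

    def test_single_subtype_equals_pooled(self, tiny_dataset):
        rep = run_loocv(tiny_dataset, {"c": ConstantModel()})
        per = subtype_auc(rep, np.array(["only"] * tiny_dataset.n_samples))["c"]
        assert per["only"] == pytest.approx(rep.auc_scores[("c", "all")])

    def test_subtype_internal_loocv_runs_per_subtype(self, small_cohort):
        out = run_subtype_specific_loocv(small_cohort, PooledLogistic)
        assert set(out) == set(np.unique(small_cohort.subtypes))


def test_five_fold_ordering_pcmt_median_pc_pooled():
    """Qualitative heterogeneity ordering: over seeds, median PCMT 5-fold AUC
    at least matches the median single-threshold PC (ensembling is no worse
    than an uninformed threshold choice) and beats the pooled model. Single-PC
    AUCs are read off the PCMT per-threshold probabilities."""
    diffs_med, diffs_lr = [], []
    for seed in range(5):
        d = generate_cohort(
            GeneratorConfig(n_samples=150, n_genes=80, n_subtypes=3, seed=100 + seed)
        )
        clf = PCMTClassifier()
        lr = PooledLogistic()
        pcmt_aucs, lr_aucs = [], []
        pc_aucs = {t: [] for t in clf.thresholds}
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(d.matrix, d.labels):
            train, test = d.subset_samples(train_idx), d.subset_samples(test_idx)
            records = clf.fit(train).predict_records(test)
            y = test.labels
            pcmt_aucs.append(auc(y, [r.pcmt_prob for r in records]))
            for t in clf.thresholds:
                pc_aucs[t].append(auc(y, [r.per_threshold_probs[t] for r in records]))
            lr_aucs.append(auc(y, lr.fit(train).predict_proba(test)))
        med_pc = float(np.median([np.mean(v) for v in pc_aucs.values()]))
        diffs_med.append(np.mean(pcmt_aucs) - med_pc)
        diffs_lr.append(med_pc - np.mean(lr_aucs))
    assert np.median(diffs_med) >= -0.01  # ensembling >= typical single PC
    assert np.median(diffs_lr) > 0  # personalized selection beats pooling
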