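"""Metrics and statistics against independent oracles; split hygiene."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from skelact import (
    ConfusionMatrix,
    cross_subject_split,
    mcc_multiclass,
    one_way_anova,
    pairwise_t_test,
    run_experiment,
)
from skelact.evaluation import confusion_matrix
from skelact.nn.model import TrainingConfig
from skelact.synthetic import CollectionProtocol, generate_dataset


def anova_by_hand(groups):
    """Sums-of-squares one-way ANOVA, written straight from the textbook."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g, float) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def t_by_hand(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    return t, df


class TestConfusionAndAccuracy:
    def test_perfect_predictions(self):
        cm = confusion_matrix(["a"] * 5 + ["b"] * 5, ["a"] * 5 + ["b"] * 5, ["a", "b"])
        assert cm.accuracy() == 100.0
        assert cm.per_class_accuracy() == {"a": 100.0, "b": 100.0}

    def test_collapsed_predictor(self):
        cm = confusion_matrix(
            ["a"] * 5 + ["b"] * 5, ["a"] * 10, ["a", "b"]
        )
        assert cm.accuracy() == 50.0
        assert cm.per_class_accuracy() == {"a": 100.0, "b": 0.0}

    def test_printed_toy_confusion(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ("x", "y"))
        assert cm.accuracy() == 85.0
        assert cm.per_class_accuracy() == {"x": 80.0, "y": 90.0}

    def test_empty_true_class_reported_missing(self):
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ("x", "y"))
        assert cm.per_class_accuracy()["y"] is None

    def test_matrix_accuracy_equals_prediction_list_accuracy(self):
        rng = np.random.default_rng(4)
        classes = ["a", "b", "c"]
        true = rng.choice(classes, 60).tolist()
        pred = rng.choice(classes, 60).tolist()
        cm = confusion_matrix(true, pred, classes)
        direct = 100.0 * np.mean([t == p for t, p in zip(true, pred)])
        assert cm.accuracy() == pytest.approx(direct)


class TestMCC:
    def test_perfect_diagonal_is_one(self):
        assert mcc_multiclass(np.diag([3, 4, 5])) == pytest.approx(1.0)

    def test_single_column_degenerate_is_zero(self):
        cm = np.array([[5, 0], [5, 0]])
        assert mcc_multiclass(cm) == 0.0

    def test_binary_case_matches_closed_form(self):
        tp, fn, fp, tn = 8, 2, 1, 9
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        got = mcc_multiclass(np.array([[tp, fn], [fp, tn]]))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(0.7035, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_on_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        true = rng.integers(0, k, 200)
        pred = rng.integers(0, k, 200)
        counts = np.zeros((k, k), dtype=int)
        for t, p in zip(true, pred):
            counts[t, p] += 1
        assert mcc_multiclass(counts) == pytest.approx(
            matthews_corrcoef(true, pred), abs=1e-9
        )


class TestANOVA:
    def test_identical_groups_give_zero_f(self):
        f, dfb, dfw, p = one_way_anova([[1, 2, 3]] * 3)
        assert f == pytest.approx(0.0)

    def test_shifted_triples_by_hand(self):
        f, dfb, dfw, p = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert (f, dfb, dfw) == (pytest.approx(3.0), 2, 6)

    def test_df_convention_six_groups_of_twenty(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=20) for _ in range(6)]
        _, dfb, dfw, _ = one_way_anova(groups)
        assert (dfb, dfw) == (5, 114)

    def test_zero_variance_everywhere_warns_infinite(self):
        with pytest.warns(UserWarning):
            f, *_ = one_way_anova([[1, 1], [2, 2]])
        assert np.isinf(f)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        groups = [
            rng.normal(rng.uniform(-2, 2), 1.0, size=int(rng.integers(3, 12)))
            for _ in range(int(rng.integers(2, 6)))
        ]
        f, dfb, dfw, p = one_way_anova(groups)
        f_ref, dfb_ref, dfw_ref = anova_by_hand(groups)
        assert f == pytest.approx(f_ref, abs=1e-9)
        assert (dfb, dfw) == (dfb_ref, dfw_ref)


class TestTTest:
    def test_identical_samples(self):
        t, df, p = pairwise_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)  # one-sided

    def test_shifted_triples_by_hand(self):
        t, df, p = pairwise_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4

    def test_df_convention_twenty_runs_each(self):
        rng = np.random.default_rng(1)
        _, df, _ = pairwise_t_test(rng.normal(size=20), rng.normal(size=20))
        assert df == 38

    def test_two_sided_doubles_symmetric_tail(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=15), rng.normal(0.5, 1, size=15)
        t1, _, p1 = pairwise_t_test(a, b, one_sided=True)
        t2, _, p2 = pairwise_t_test(a, b, one_sided=False)
        assert t1 == t2
        expected = 2 * min(p1, 1 - p1)
        assert p2 == pytest.approx(expected, abs=1e-12)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            pairwise_t_test([1, 1], [1, 1])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_hand_computation(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=int(rng.integers(3, 25)))
        b = rng.normal(0.3, 1.2, size=int(rng.integers(3, 25)))
        t, df, _ = pairwise_t_test(a, b)
        t_ref, df_ref = t_by_hand(a, b)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert df == df_ref


class TestCrossSubjectSplit:
    def test_tsbd_style_split_sizes(self, small_dataset):
        # scaled-down shape check; full-protocol arithmetic is covered in
        # the acceptance suite
        tr, va, te = cross_subject_split(small_dataset, 2, 1, 1, seed=0)
        assert (len(tr), len(va), len(te)) == (90, 45, 45)

    def test_degenerate_all_train(self, small_dataset):
        tr, va, te = cross_subject_split(small_dataset, 4, 0, 0, seed=0)
        assert len(tr) == len(small_dataset)
        assert len(va) == len(te) == 0

    def test_insufficient_subjects_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            cross_subject_split(small_dataset, 10, 5, 5, seed=0)

    def test_no_subject_leaks_property(self, small_dataset):
        for seed in range(30):
            tr, va, te = cross_subject_split(small_dataset, 2, 1, 1, seed=seed)
            s = [set(tr.subjects), set(va.subjects), set(te.subjects)]
            assert not (s[0] & s[1] or s[0] & s[2] or s[1] & s[2])
            assert len(tr) + len(va) + len(te) == len(small_dataset)

    def test_split_deterministic_in_seed(self, small_dataset):
        a = cross_subject_split(small_dataset, 2, 1, 1, seed=9)
        b = cross_subject_split(small_dataset, 2, 1, 1, seed=9)
        assert [x.subjects for x in a] == [x.subjects for x in b]


class TestExperimentHarness:
    def test_reduced_experiment_report_is_well_formed(self):
        ds = generate_dataset(CollectionProtocol(n_subjects=5, master_seed=3))
        cfg = TrainingConfig(epochs=5, runs=3)
        report = run_experiment(
            "E1",
            ds,
            cfg,
            split=(3, 1, 1),
            orderings=("B1", "B6"),
        )
        assert set(report.runs) == {"B1", "B6"}
        assert all(len(v) == 3 for v in report.runs.values())
        assert report.anova_df[0] == 1  # two configurations
        assert "B6" in report.t_tests
        t, df, p = report.t_tests["B6"]
        assert df == 4  # 3 + 3 − 2
        table = report.mean_sd()
        assert set(table["ordering"]) == {"B1", "B6"}
        assert ((table["mean_acc"] >= 0) & (table["mean_acc"] <= 100)).all()
        text = report.summary()
        assert "ANOVA" in text and "B6" in text

    def test_full_experiment_df_shapes(self):
        # the df bookkeeping for the full designs, without training:
        # six orderings × 20 runs → F(5, 114); pairwise 20+20 → t(38)
        rng = np.random.default_rng(0)
        groups = [list(90 + rng.normal(size=20)) for _ in range(6)]
        _, dfb, dfw, _ = one_way_anova(groups)
        assert (dfb, dfw) == (5, 114)
        _, df, _ = pairwise_t_test(groups[0], groups[1])
        assert df == 38
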