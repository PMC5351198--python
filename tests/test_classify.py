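"""Metrics, balancing and Monte Carlo cross-validation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)

from mirclade import (
    FeatureMatrix,
    SplitPlan,
    balance_classes,
    compute_metrics,
    mccv_run,
    run_motif_recreation_experiment,
)
from mirclade.synthetic import disjoint_motif_spec, generate_dataset

from conftest import make_dataset


def matrix_from_arrays(X, y):
    frame = pd.DataFrame(np.asarray(X, dtype=float), columns=[f"f{i}" for i in range(np.shape(X)[1])])
    frame.index = [f"e{i}" for i in range(np.shape(X)[0])]
    return FeatureMatrix(X=frame, y=pd.Series(list(y), index=frame.index))


class TestMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(5, 0, 5, 0)
        assert m == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_total_inversion(self):
        m = compute_metrics(0, 5, 0, 5)
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_zero_denominators_define_metric_as_zero(self):
        m = compute_metrics(0, 0, 10, 0)  # no positives predicted or present
        assert m.se == 0.0 and m.precision == 0.0 and m.f_measure == 0.0
        assert m.mcc == 0.0
        assert m.acc == 1.0

    def test_negative_counts_are_an_error(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 1)

    def test_matches_sklearn_on_random_confusion_tables(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 40, size=4))
            if tp + fp + tn + fn == 0:
                continue
            y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
            y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
            m = compute_metrics(tp, fp, tn, fn)
            assert m.acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert m.se == pytest.approx(recall_score(y_true, y_pred, zero_division=0))
            assert m.precision == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0)
            )
            assert m.f_measure == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
            if len(set(y_true)) == 2 and len(set(y_pred)) == 2:
                assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_acc_equals_weighted_se_sp(self, rng):
        for _ in range(30):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 40, size=4))
            m = compute_metrics(tp, fp, tn, fn)
            p, n = tp + fn, tn + fp
            assert m.acc == pytest.approx((m.se * p + m.sp * n) / (p + n))


class TestBalance:
    def test_downsamples_majority_to_minority(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(160, 3)), ["a"] * 100 + ["b"] * 60)
        balanced = balance_classes(fm, seed=0)
        assert balanced.y.value_counts().tolist() == [60, 60]

    def test_already_balanced_is_unchanged(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(40, 3)), ["a", "b"] * 20)
        balanced = balance_classes(fm, seed=0)
        assert balanced.X.index.tolist() == fm.X.index.tolist()

    def test_missing_class_is_an_error(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(10, 2)), ["a"] * 10)
        with pytest.raises(ValueError):
            balance_classes(fm)

    def test_uniform_sampling_frequency(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(1100, 2)), ["a"] * 1000 + ["b"] * 100)
        kept = np.zeros(1000)
        n_seeds = 50
        for seed in range(n_seeds):
            balanced = balance_classes(fm, seed=seed)
            kept_ids = {i for i in balanced.X.index}
            for pos in range(1000):
                if f"e{pos}" in kept_ids:
                    kept[pos] += 1
        freq = kept / n_seeds
        # each majority example retained with frequency ~0.1 +- binomial error
        assert abs(freq.mean() - 0.1) < 1e-9
        binom_sd = np.sqrt(0.1 * 0.9 / n_seeds)
        assert 0.7 * binom_sd < freq.std() < 1.3 * binom_sd


def separable_matrix(rng, n=100):
    y = np.array(["positive"] * (n // 2) + ["negative"] * (n // 2))
    X = rng.normal(size=(n, 5))
    X[:, 0] = np.where(y == "positive", 5.0, -5.0) + rng.normal(scale=0.1, size=n)
    return matrix_from_arrays(X, y)


class TestMccv:
    def test_separable_data_gives_perfect_accuracy(self, rng):
        fm = separable_matrix(rng)
        plan = SplitPlan(n_folds=1, seed=0)
        report = mccv_run(fm, plan, n_trees=20)
        assert report.mean_metrics("test").acc == 1.0
        assert report.mean_metrics("holdout").acc == 1.0

    def test_deterministic_given_seed(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(60, 6)), ["positive", "negative"] * 30)
        plan = SplitPlan(n_folds=4, seed=11)
        r1 = mccv_run(fm, plan, n_trees=15)
        r2 = mccv_run(fm, plan, n_trees=15)
        assert [f.test_counts for f in r1.folds] == [f.test_counts for f in r2.folds]
        assert [f.holdout_counts for f in r1.folds] == [f.holdout_counts for f in r2.folds]

    def test_counts_cover_partitions_every_fold(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(100, 4)), ["positive", "negative"] * 50)
        plan = SplitPlan(n_folds=5, seed=3)
        report = mccv_run(fm, plan, n_trees=10)
        n_hold = round(100 * plan.holdout_fraction)
        n_test = round((100 - n_hold) * plan.test_fraction)
        for f in report.folds:
            assert sum(f.test_counts) == n_test
            assert sum(f.holdout_counts) == n_hold

    def test_label_permutation_gives_near_zero_mcc(self, rng):
        # predictions independent of labels => mean MCC ~ 0
        X = rng.normal(size=(80, 6))
        mccs = []
        for perm in range(100):
            y = rng.permutation(["positive", "negative"] * 40)
            fm = matrix_from_arrays(X, y)
            plan = SplitPlan(n_folds=1, seed=perm)
            report = mccv_run(fm, plan, n_trees=10)
            mccs.append(report.folds[0].test_metrics.mcc)
        assert abs(np.mean(mccs)) < 0.05

    def test_single_class_matrix_is_an_error(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(20, 3)), ["positive"] * 20)
        with pytest.raises(ValueError):
            mccv_run(fm, SplitPlan(n_folds=1, seed=0))

    def test_report_frame_and_write(self, rng, tmp_path):
        fm = separable_matrix(rng, n=60)
        report = mccv_run(fm, SplitPlan(n_folds=3, seed=0), n_trees=10)
        frame = report.to_frame()
        assert len(frame) == 6  # 3 folds x 2 partitions
        path = tmp_path / "report.tsv"
        report.write(path)
        text = path.read_text()
        assert "summary" in text and "holdout" in text

    def test_mean_lies_within_per_fold_range(self, rng):
        fm = matrix_from_arrays(rng.normal(size=(80, 6)), ["positive", "negative"] * 40)
        report = mccv_run(fm, SplitPlan(n_folds=6, seed=2), n_trees=10)
        dist = report.accuracy_distribution("test")
        assert dist.min() <= report.mean_metrics("test").acc <= dist.max()


class TestRecreationExperiment:
    def test_single_outer_fold_with_full_subset_reduces_to_mode_a(self):
        spec = disjoint_motif_spec(n_per_class=60, divergence=1.0, seed=4)
        pos, neg = generate_dataset(spec)
        report_a, report_b = run_motif_recreation_experiment(
            pos,
            neg,
            outer_folds=1,
            inner_folds=3,
            n_motifs=5,
            n_selected=50,
            n_trees=15,
            subset_fraction=1.0,
            seed=4,
        )
        assert [f.test_counts for f in report_a.folds] == [
            f.test_counts for f in report_b.folds
        ]
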