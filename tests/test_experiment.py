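"""Split management, evaluation metrics, the statistical comparison protocol,
grid search hygiene and benchmark bookkeeping."""

import numpy as np
import pytest

from graphomics import nn
from graphomics.experiment import (
    DEFAULT_GAMMA_GRID,
    DEFAULT_WEIGHT_GRID,
    TrainConfig,
    candidate_configs,
    ci95,
    cohens_d,
    confusion_counts,
    evaluate,
    grid_search,
    paired_ttest,
    run_benchmark,
    stratified_split,
)
from graphomics.graphs import SimilarityConfig, build_graph

FAST = dict(max_epochs=40, patience=10)


class TestStratifiedSplit:
    def test_balanced_seventy_thirty(self):
        labels = np.repeat([0, 1], 50)
        plan = stratified_split(labels, 0.7, seed=0)
        for c in (0, 1):
            assert np.sum(labels[plan.train_side] == c) == 35
            assert np.sum(labels[plan.test_idx] == c) == 15

    def test_same_seed_same_plan(self):
        labels = np.repeat([0, 1, 2], 20)
        a = stratified_split(labels, 0.7, seed=5, val_fraction_of_train=0.1)
        b = stratified_split(labels, 0.7, seed=5, val_fraction_of_train=0.1)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.val_idx, b.val_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_sets_disjoint_exhaustive_and_ratio_within_one(self, rng):
        for trial in range(20):
            labels = rng.integers(0, 3, 40)
            while (np.bincount(labels, minlength=3) < 2).any():
                labels = rng.integers(0, 3, 40)
            plan = stratified_split(labels, 0.7, seed=trial, val_fraction_of_train=0.1)
            allidx = np.concatenate([plan.train_idx, plan.val_idx, plan.test_idx])
            assert sorted(allidx) == list(range(40))
            for c in range(3):
                n_c = np.sum(labels == c)
                got = np.sum(labels[plan.train_side] == c)
                assert abs(got - 0.7 * n_c) <= 1

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 0, 1]), 0.7, seed=0)


def oracle_metrics(y_true, y_pred, classes):
    """Literal per-class one-vs-rest confusion arithmetic."""
    sens, spec, prec, f1s, sup = [], [], [], [], []
    for c in classes:
        tp = np.sum((y_true == c) & (y_pred == c))
        tn = np.sum((y_true != c) & (y_pred != c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        if tp + fn == 0:
            continue
        r = tp / (tp + fn)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        s = tn / (tn + fp) if tn + fp > 0 else np.nan  # class covers whole set
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        sens.append(r), spec.append(s), prec.append(p), f1s.append(f1), sup.append(tp + fn)
    sup = np.array(sup, dtype=float)
    return {
        "accuracy": np.mean(y_true == y_pred),
        "sensitivity": np.mean(sens),
        "specificity": np.nanmean(spec) if not np.all(np.isnan(spec)) else np.nan,
        "precision": np.mean(prec),
        "f1_macro": np.mean(f1s),
        "f1_weighted": np.sum(np.array(f1s) * sup / sup.sum()),
    }


class TestEvaluate:
    def test_binary_counts_worked_example(self):
        # TP=3, FP=1, TN=4, FN=2 for the positive class
        y_true = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        counts = confusion_counts(y_true, y_pred, positive=1)
        assert counts == {"TP": 3, "TN": 4, "FP": 1, "FN": 2}
        assert (counts["TP"] + counts["TN"]) / 10 == pytest.approx(0.7)
        assert counts["TP"] / (counts["TP"] + counts["FP"]) == pytest.approx(0.75)
        recall = counts["TP"] / (counts["TP"] + counts["FN"])
        assert recall == pytest.approx(0.6)
        assert 2 * 0.75 * recall / (0.75 + recall) == pytest.approx(2 / 3)

    def test_perfect_predictions(self):
        probs = np.eye(3)[np.array([0, 1, 2, 0, 1, 2])]
        labels = np.array([0, 1, 2, 0, 1, 2])
        m = evaluate(probs, labels)
        assert all(m[k] == pytest.approx(1.0) for k in m)

    def test_constant_probabilities_give_auc_half(self):
        probs = np.full((8, 2), 0.5)
        labels = np.array([0, 1] * 4)
        assert evaluate(probs, labels)["auc_macro"] == pytest.approx(0.5)

    def test_matches_confusion_oracle_on_random_cases(self, rng):
        for _ in range(300):
            c = int(rng.integers(2, 5))
            n = int(rng.integers(4, 20))
            labels = rng.integers(0, c, n)
            probs = rng.uniform(0.01, 1, (n, c))
            probs /= probs.sum(axis=1, keepdims=True)
            preds = np.argmax(probs, axis=1)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = evaluate(probs, labels)
            want = oracle_metrics(labels, preds, range(c))
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-12, nan_ok=True), key


class TestStatistics:
    def test_paired_ttest_worked_example(self):
        # differences (1, 2, 3): t = 2/(1/sqrt(3)) ~ 3.4641, p ~ 0.0742
        p = paired_ttest(np.array([2.0, 3, 4]), np.array([1.0, 1, 1]))
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_paired_ttest_degenerate_cases(self):
        assert paired_ttest([1.0, -1.0], [0.0, 0.0]) == 1.0  # t = 0
        assert paired_ttest([1.0, 2.0], [1.0, 2.0]) == 1.0  # all-zero differences
        assert paired_ttest([2.0, 3.0], [1.0, 2.0]) == 0.0  # constant nonzero diff

    def test_cohens_d_worked_example_and_antisymmetry(self):
        a, b = np.array([1.0, 2, 3]), np.array([3.0, 4, 5])
        assert cohens_d(a, b) == pytest.approx(-2.0)
        assert cohens_d(b, a) == pytest.approx(2.0)
        assert cohens_d(a, a) == 0.0

    def test_ci95_worked_example(self):
        lo, hi = ci95([0.89, 0.90, 0.91])
        assert lo == pytest.approx(0.87516, abs=1e-4)
        assert hi == pytest.approx(0.92484, abs=1e-4)

    def test_ci95_degenerate(self):
        assert ci95([0.5, 0.5, 0.5]) == (0.5, 0.5)
        lo, hi = ci95([0.2, 0.4, 0.9])
        assert lo <= np.mean([0.2, 0.4, 0.9]) <= hi


class TestTraining:
    def test_loss_decreases_and_train_accuracy_reaches_one(self, small_dataset):
        ds = small_dataset
        mats = [v.values for v in ds.views]
        graphs = [build_graph(X, SimilarityConfig(k=5)) for X in mats]
        train_idx = np.arange(0, 30)
        val_idx = np.arange(30, 36)
        _, _, probs, hist = nn.train_joint(
            mats, graphs, ds.labels, train_idx, val_idx, n_classes=2,
            max_epochs=60, patience=60, seed=0,
        )
        first10 = hist.train_loss[:10]
        assert all(a > b for a, b in zip(first10, first10[1:]))
        preds = np.argmax(probs["fused"][train_idx], axis=1)
        assert np.mean(preds == ds.labels[train_idx]) == 1.0

    def test_zero_learning_rate_patience_one_stops_at_epoch_two(self, small_dataset):
        ds = small_dataset
        mats = [v.values for v in ds.views]
        graphs = [build_graph(X, SimilarityConfig(k=5)) for X in mats]
        _, _, _, hist = nn.train_joint(
            mats, graphs, ds.labels, np.arange(30), np.arange(30, 36), n_classes=2,
            learning_rate=0.0, patience=1, max_epochs=100, seed=0,
        )
        assert hist.stopped_epoch == 2

    def test_same_seed_identical_parameters(self, small_dataset):
        ds = small_dataset
        mats = [v.values for v in ds.views]
        graphs = [build_graph(X, SimilarityConfig(k=5)) for X in mats]
        runs = [
            nn.train_joint(mats, graphs, ds.labels, np.arange(30), np.arange(30, 36),
                           n_classes=2, max_epochs=25, patience=25, seed=4)
            for _ in range(2)
        ]
        for ga, gb in zip(runs[0][0], runs[1][0]):
            assert np.array_equal(ga.theta0, gb.theta0)
            assert np.array_equal(ga.theta1, gb.theta1)
        assert np.array_equal(runs[0][2]["fused"], runs[1][2]["fused"])


class TestGridSearch:
    def test_single_point_grid_returned(self, small_dataset):
        cfg = grid_search(
            [v.values for v in small_dataset.views], small_dataset.labels,
            np.arange(30), "rbf_similarity", gamma_grid=(0.3,), k=5, **FAST,
        )
        assert cfg.metric == "rbf_similarity" and cfg.gamma == 0.3

    def test_hybrid_candidate_count_is_thirty(self):
        cands = candidate_configs("hybrid_similarity", DEFAULT_GAMMA_GRID, DEFAULT_WEIGHT_GRID)
        assert len(cands) == 30
        assert len(candidate_configs("cosine_similarity")) == 1
        assert len(candidate_configs("rbf_distance")) == 6

    def test_selection_ignores_test_labels(self, small_dataset):
        ds = small_dataset
        views = [v.values for v in ds.views]
        train_idx = np.arange(0, 28)
        labels_poisoned = ds.labels.copy()
        labels_poisoned[28:] = 1 - labels_poisoned[28:]
        kw = dict(metric="rbf_similarity", gamma_grid=(0.01, 1.0), k=5, seed=0, **FAST)
        a = grid_search(views, ds.labels, train_idx, **kw)
        b = grid_search(views, labels_poisoned, train_idx, **kw)
        assert a == b


@pytest.fixture(scope="module")
def tiny_report(small_dataset):
    cfg = TrainConfig(max_epochs=30, patience=30, seeds=(0, 1), k=5)
    configs = {
        "cosine_similarity": SimilarityConfig(metric="cosine_similarity", k=5),
        "rbf_similarity": SimilarityConfig(metric="rbf_similarity", k=5),
    }
    return run_benchmark(
        [v.values for v in small_dataset.views], small_dataset.labels,
        configs=configs, variants=("full", "no_vcdn"), train_config=cfg,
    )


class TestBenchmark:
    def test_row_bookkeeping(self, tiny_report):
        per_split = tiny_report.per_split
        assert len(per_split) == 2 * 2 * 2  # metrics x variants x seeds
        assert set(per_split["metric"]) == {"cosine_similarity", "rbf_similarity"}

    def test_summary_mean_matches_per_split(self, tiny_report):
        per_split, summary = tiny_report.per_split, tiny_report.summary
        row = summary[
            (summary["metric"] == "cosine_similarity")
            & (summary["variant"] == "full")
            & (summary["measure"] == "accuracy")
        ].iloc[0]
        grp = per_split[
            (per_split["metric"] == "cosine_similarity") & (per_split["variant"] == "full")
        ]
        assert row["mean"] == pytest.approx(grp["accuracy"].mean())

    def test_duplicated_seed_gives_zero_sd(self, small_dataset):
        cfg = TrainConfig(max_epochs=20, patience=20, seeds=(3, 3), k=5)
        rep = run_benchmark(
            [v.values for v in small_dataset.views], small_dataset.labels,
            configs={"cosine_similarity": SimilarityConfig(k=5)},
            train_config=cfg,
        )
        assert (rep.summary["sd"] == 0).all()

    def test_csv_bytes_deterministic(self, small_dataset, tmp_path):
        cfg = TrainConfig(max_epochs=20, patience=20, seeds=(0,), k=5)
        outs = []
        for name in ("a", "b"):
            rep = run_benchmark(
                [v.values for v in small_dataset.views], small_dataset.labels,
                configs={"cosine_similarity": SimilarityConfig(k=5)},
                train_config=cfg,
            )
            rep.to_csv(tmp_path / name)
            outs.append((tmp_path / name / "per_split.csv").read_bytes())
        assert outs[0] == outs[1]
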