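import numpy as np
import pytest

from swdpredict import (FeatureTable, SamplingPlan,
                        build_balanced_training_set, chronological_split,
                        classify_events, forest_size_curve, load_model,
                        save_model, select_representative_forest,
                        train_random_forest)
from swdpredict.classifier import balanced_accuracy, labeled_subset
from swdpredict.detector import DetectionEvent

from conftest import separable_features


def _event(t, label, features=None):
    ev = DetectionEvent(
        t=t,
        features=np.ones(9) if features is None else np.asarray(features),
        products=np.ones(3),
        channels=("S1_L4", "S1_L5", "S1_L6"),
        band_names=("precursor", "sws", "spindle"))
    ev.label = label
    return ev


def _event_pool(n_tp, n_fp, rng_seed=0, t_max=100.0, separated=True):
    rng = np.random.default_rng(rng_seed)
    X, y = separable_features(max(n_tp, n_fp), rng_seed,
                              tp_mean=3.0 if separated else 1.0)
    tps = [_event(rng.uniform(0, t_max), "TP", X[i]) for i in range(n_tp)]
    fps = [_event(rng.uniform(0, t_max), "FP",
                  X[max(n_tp, n_fp) + i]) for i in range(n_fp)]
    return tps + fps


class TestBalancedTrainingSet:
    def test_undersample_counts(self):
        table = build_balanced_training_set(
            _event_pool(100, 5000), SamplingPlan(mode="undersample",
                                                 rng_seed=0))
        assert table.X.shape[0] == 200
        assert table.n_tp == 100 and table.n_fp == 100

    def test_oversample_factor_4(self):
        table = build_balanced_training_set(
            _event_pool(100, 5000),
            SamplingPlan(mode="oversample", oversample_factor=4, rng_seed=0))
        assert table.X.shape[0] == 800
        assert table.n_tp == 400 and table.n_fp == 400

    def test_fp_pool_too_small(self):
        with pytest.raises(ValueError, match="400"):
            build_balanced_training_set(
                _event_pool(100, 150),
                SamplingPlan(mode="oversample", oversample_factor=4))

    def test_too_few_tps(self):
        with pytest.raises(ValueError):
            build_balanced_training_set(_event_pool(3, 100), SamplingPlan())

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            SamplingPlan(mode="smote")
        with pytest.raises(ValueError):
            SamplingPlan(mode="oversample", oversample_factor=1)


class TestChronologicalSplit:
    def test_no_leakage(self):
        events = _event_pool(50, 200, t_max=1000.0)
        train, heldout = chronological_split(events, duration_s=1000.0)
        t_train = [e.t for e in train]
        t_eval = [e.t for e in heldout]
        assert max(t_train) < 700.0 <= min(t_eval)
        assert len(train) + len(heldout) == len(labeled_subset(events))


class TestForestTraining:
    def test_separable_recovery(self):
        """Stated class distributions (precursor band N(3, 0.25) vs
        N(1, 0.25)) are recovered with >= 95% held-out balanced
        accuracy."""
        X, y = separable_features(500, rng_seed=1)
        table = FeatureTable(X=X, y=y)
        model = train_random_forest(table, n_trees=200, rng_seed=0)
        X_eval, y_eval = separable_features(300, rng_seed=2)
        assert balanced_accuracy(model, X_eval, y_eval) >= 95.0

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(3)
        X, y = separable_features(500, rng_seed=3)
        table = FeatureTable(X=X, y=rng.permutation(y))
        model = train_random_forest(table, n_trees=200, rng_seed=0)
        X_eval, y_eval = separable_features(300, rng_seed=4)
        acc = balanced_accuracy(model, X_eval, y_eval)
        assert 45.0 <= acc <= 55.0

    def test_deterministic_given_seed(self):
        X, y = separable_features(100, rng_seed=5, tp_mean=1.5)
        table = FeatureTable(X=X, y=y)
        m1 = train_random_forest(table, n_trees=50, rng_seed=11)
        m2 = train_random_forest(table, n_trees=50, rng_seed=11)
        X_eval, _ = separable_features(100, rng_seed=6, tp_mean=1.5)
        assert np.array_equal(m1.predict(X_eval), m2.predict(X_eval))

    def test_single_class_rejected(self):
        X, _ = separable_features(20, rng_seed=7)
        with pytest.raises(ValueError):
            train_random_forest(FeatureTable(X=X, y=np.ones(40, int)))

    def test_feature_dimension_checked(self):
        X, y = separable_features(50, rng_seed=8)
        model = train_random_forest(FeatureTable(X=X, y=y), n_trees=20)
        with pytest.raises(ValueError):
            model.predict(np.ones((3, 6)))


class TestRepresentativeForest:
    def test_returns_requested_accuracies(self):
        train = _event_pool(20, 200, rng_seed=0)
        heldout = _event_pool(20, 100, rng_seed=1)
        model, accs = select_representative_forest(
            train, heldout, SamplingPlan(mode="undersample"),
            n_forests=5, n_trees=30, base_seed=0)
        assert accs.shape == (5,)
        X = np.stack([e.features for e in labeled_subset(heldout)])
        y = np.array([1 if e.label == "TP" else 0
                      for e in labeled_subset(heldout)])
        chosen = balanced_accuracy(model, X, y)
        assert abs(chosen - accs.mean()) <= max(accs.std(ddof=0), 1e-9) + 1e-9


class TestClassifyEvents:
    def test_all_tp_model_changes_nothing(self):
        events = _event_pool(10, 40, rng_seed=2)
        # train on classes that straddle a boundary far below every
        # observed event feature, so every event is voted TP
        X = np.vstack([np.full((50, 9), 1e-3), np.full((50, 9), 1e-4)])
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        model = train_random_forest(FeatureTable(X=X, y=y), n_trees=30)
        out = classify_events(model, events)
        assert out.fp_reduction_pct == 0.0
        assert len(out.kept_events) == len(events)

    def test_all_fp_model_suppresses_everything(self):
        events = _event_pool(10, 40, rng_seed=3)
        X = np.vstack([np.full((50, 9), 100.0), np.full((50, 9), 50.0)])
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        model = train_random_forest(FeatureTable(X=X, y=y), n_trees=30)
        out = classify_events(model, events)
        assert out.fp_reduction_pct == 100.0
        assert len(out.kept_events) == 0

    def test_filtering_only_removes(self):
        events = _event_pool(30, 120, rng_seed=4)
        table = build_balanced_training_set(
            events, SamplingPlan(mode="undersample", rng_seed=0))
        model = train_random_forest(table, n_trees=50)
        out = classify_events(model, events)
        kept_tp = sum(e.label == "TP" for e in out.kept_events)
        assert kept_tp <= 30
        assert len(out.kept_events) + len(out.suppressed_events) == 150


class TestForestSizeCurve:
    def test_single_size(self):
        X, y = separable_features(50, rng_seed=9)
        table = FeatureTable(X=X, y=y)
        events = _event_pool(20, 20, rng_seed=10)
        curve = forest_size_curve(table, [1], events)
        assert len(curve) == 1 and curve[0][0] == 1

    def test_larger_forests_not_worse(self):
        """Across seeds, a 101-tree forest is at worst marginally below a
        single tree on noisy separable data."""
        wins = 0
        for seed in range(10):
            X, y = separable_features(120, rng_seed=seed, tp_mean=1.8)
            table = FeatureTable(X=X, y=y)
            events = _event_pool(40, 40, rng_seed=100 + seed, separated=True)
            for e in events:  # rescale eval pool to the same contrast
                if e.label == "TP":
                    e.features[:3] = e.features[:3] / 3.0 * 1.8
            curve = dict(forest_size_curve(table, [1, 101], events,
                                           rng_seed=seed))
            wins += curve[101] >= curve[1] - 2.0
        assert wins >= 8

    def test_invalid_size_rejected(self):
        X, y = separable_features(20, rng_seed=11)
        with pytest.raises(ValueError):
            forest_size_curve(FeatureTable(X=X, y=y), [0], [])


class TestPersistence:
    def test_round_trip(self, tmp_path):
        X, y = separable_features(60, rng_seed=12)
        model = train_random_forest(FeatureTable(X=X, y=y), n_trees=40,
                                    rng_seed=3)
        path = save_model(model, tmp_path / "model.joblib")
        back = load_model(path)
        X_eval, _ = separable_features(50, rng_seed=13)
        assert np.array_equal(model.predict(X_eval), back.predict(X_eval))
        assert back.n_trees == 40 and back.seed == 3
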