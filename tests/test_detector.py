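"""Feature selection, MLP training and the evaluation metrics."""

import numpy as np
import pytest

from fcdetect.detector import (
    Metrics,
    MLPConfig,
    SelectionConfig,
    evaluate,
    select_features,
    train_mlp,
    youden_threshold,
)

from .oracles import allpairs_auc


class TestSelectFeatures:
    def test_planted_feature_retained(self):
        """One perfectly predictive feature among pure noise survives the
        tuned importance threshold in nearly every replicate."""
        hits = 0
        n_rep = 6
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 80
            y = rng.integers(0, 2, n)
            X = rng.normal(size=(n, 12))
            X[:, 4] = y + 0.05 * rng.normal(size=n)
            cfg = SelectionConfig(n_trees=100, threshold_grid_size=10, eval_trees=25, cv_folds=3, seed=seed)
            kept = select_features(X, y, cfg)
            hits += "f4" in kept
        assert hits >= n_rep - 1

    def test_never_empty(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, 40)
        cfg = SelectionConfig(n_trees=50, threshold_grid_size=5, eval_trees=10, cv_folds=2, seed=0)
        assert len(select_features(X, y, cfg)) >= 1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 8))
        y = (X[:, 2] > 0).astype(int)
        cfg = SelectionConfig(n_trees=60, threshold_grid_size=6, eval_trees=20, cv_folds=3, seed=5)
        assert select_features(X, y, cfg) == select_features(X, y, cfg)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            select_features(rng.normal(size=(10, 3)), np.zeros(10), SelectionConfig())


class TestMLP:
    def test_separable_clusters_reach_perfect_training_accuracy(self, rng):
        n = 40
        X = np.vstack([rng.normal(-3, 0.3, (n, 4)), rng.normal(3, 0.3, (n, 4))])
        y = np.repeat([0, 1], n)
        model = train_mlp(X, y, MLPConfig(seed=0, epochs=300))
        acc = ((model.decision_scores(X) >= 0.5).astype(int) == y).mean()
        assert acc == 1.0

    def test_same_seed_identical_scores(self, rng):
        X = rng.normal(size=(50, 6))
        y = rng.integers(0, 2, 50)
        s1 = train_mlp(X, y, MLPConfig(seed=7)).decision_scores(X)
        s2 = train_mlp(X, y, MLPConfig(seed=7)).decision_scores(X)
        assert np.array_equal(s1, s2)

    def test_scores_are_probabilities(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        p = train_mlp(X, y, MLPConfig(seed=1)).predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert (p >= 0).all()

    def test_permutation_null_auc_near_half(self):
        """Label-permuted training gives chance-level held-out AUC."""
        aucs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(120, 6))
            y = rng.permutation(np.repeat([0, 1], 60))
            tr, te = np.arange(80), np.arange(80, 120)
            model = train_mlp(X[tr], y[tr], MLPConfig(seed=seed, epochs=100))
            aucs.append(evaluate(y[te], model.decision_scores(X[te])).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_nonfinite_input_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            train_mlp(X, np.array([0, 1]), MLPConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(input_dropout=1.0)
        with pytest.raises(ValueError):
            MLPConfig(hidden_sizes=(0, 10))


class TestEvaluate:
    def test_perfect_ranking(self):
        m = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.accuracy == 1.0

    def test_all_tied_scores(self):
        m = evaluate([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert m.auc == pytest.approx(0.5)

    def test_auc_matches_allpairs_oracle(self):
        y = [1, 0, 1, 1, 0, 0, 1, 0]
        s = [0.9, 0.8, 0.8, 0.6, 0.55, 0.3, 0.2, 0.1]
        m = evaluate(y, s)
        assert m.auc == pytest.approx(allpairs_auc(y, s))

    def test_balanced_accuracy_identity(self, rng):
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        s = rng.random(60)
        m = evaluate(y, s)
        assert m.balanced_accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        m1 = evaluate(y, s)
        m2 = evaluate(y, s**3)  # strictly monotone on [0,1]
        assert m1.auc == pytest.approx(m2.auc)
        assert m1.sensitivity == m2.sensitivity and m1.specificity == m2.specificity

    def test_youden_lowest_cut_on_ties(self):
        # two cuts achieve the same J; the lower one must be returned
        y = [0, 1, 1]
        s = [0.2, 0.6, 0.9]
        assert youden_threshold(y, s) == pytest.approx(0.6)

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning):
            m = evaluate([1, 1, 1], [0.2, 0.5, 0.9])
        assert np.isnan(m.auc)

    def test_metrics_in_unit_interval(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        m = evaluate(y, rng.random(50))
        for v in (m.accuracy, m.balanced_accuracy, m.sensitivity, m.specificity, m.auc, m.optimal_threshold):
            assert 0.0 <= v <= 1.0
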