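"""Site predictor training: class weighting, planted-signal recovery,
determinism, early stopping, metric suite."""

import numpy as np
import pytest

from abdock.site_predictors import (
    SiteBindingClassifier,
    class_weights,
    evaluate_binary,
    geometric_widths,
)

FAST = dict(widths=[48, 44, 40, 38, 36, 34, 32], max_epochs=60, patience=8)


class TestClassWeights:
    def test_binding_class_weight(self):
        assert class_weights(10, 100) == pytest.approx(5.0)

    def test_nonbinding_class_weight(self):
        assert class_weights(90, 100) == pytest.approx(0.5555555555)

    def test_balanced_classes_unit_weight(self):
        assert class_weights(50, 100) == pytest.approx(1.0)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            class_weights(0, 100)


class TestGeometricWidths:
    def test_endpoints_and_monotone(self):
        w = geometric_widths(7)
        assert w[0] == 256 and w[-1] == 32
        assert w == sorted(w, reverse=True)


def _planted_table(rng, n=900, d=25, scale=1.5):
    X = rng.normal(size=(n, d))
    w = rng.normal(size=d)
    p = 1.0 / (1.0 + np.exp(-scale * (X @ w)))
    y = (rng.random(n) < p).astype(int)
    return X, y


class TestSiteBindingClassifier:
    def test_planted_linear_signal_recovered(self):
        rng = np.random.default_rng(0)
        X, y = _planted_table(rng)
        clf = SiteBindingClassifier(n_hidden=7, random_state=1, **FAST)
        clf.fit(X[:700], y[:700])
        probs = clf.predict_proba(X[700:])[:, 1]
        m = evaluate_binary(probs, y[700:])
        assert m["roc_auc"] >= 0.95
        # logistic-fit oracle is an upper bound neighbourhood, not exceeded wildly
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(max_iter=1000).fit(X[:700], y[:700])
        oracle = evaluate_binary(lr.predict_proba(X[700:])[:, 1], y[700:])["roc_auc"]
        assert m["roc_auc"] >= oracle - 0.05

    def test_random_labels_near_chance(self):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(600, 20))
            y = rng.integers(0, 2, size=600)
            clf = SiteBindingClassifier(
                n_hidden=7, random_state=seed, max_epochs=30, patience=5,
                widths=[32] * 7,
            ).fit(X[:450], y[:450])
            aucs.append(
                evaluate_binary(clf.predict_proba(X[450:])[:, 1], y[450:])["roc_auc"]
            )
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_same_seed_identical_predictions(self):
        rng = np.random.default_rng(2)
        X, y = _planted_table(rng, n=400)
        p1 = SiteBindingClassifier(n_hidden=7, random_state=5, **FAST).fit(X, y).predict_proba(X)
        p2 = SiteBindingClassifier(n_hidden=7, random_state=5, **FAST).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_positive_mean_prob_exceeds_negative(self):
        rng = np.random.default_rng(3)
        X, y = _planted_table(rng, n=600)
        clf = SiteBindingClassifier(n_hidden=7, random_state=0, **FAST).fit(X, y)
        p = clf.predict_proba(X)[:, 1]
        assert p[y == 1].mean() > p[y == 0].mean()

    def test_single_class_raises(self):
        X = np.zeros((20, 4))
        with pytest.raises(ValueError, match="both classes"):
            SiteBindingClassifier().fit(X, np.zeros(20))

    def test_nonfinite_features_raise(self):
        X = np.full((20, 4), np.nan)
        y = np.arange(20) % 2
        with pytest.raises(ValueError, match="finite"):
            SiteBindingClassifier(widths=[8] * 7).fit(X, y)

    def test_feature_signature_checked_at_predict(self):
        rng = np.random.default_rng(4)
        X, y = _planted_table(rng, n=200, d=10)
        clf = SiteBindingClassifier(n_hidden=7, widths=[8] * 7, max_epochs=5).fit(X, y)
        with pytest.raises(ValueError, match="signature"):
            clf.predict_proba(np.zeros((3, 11)))

    def test_grouped_split_keeps_complexes_together(self):
        rng = np.random.default_rng(5)
        X, y = _planted_table(rng, n=300)
        groups = np.repeat(np.arange(10), 30)
        clf = SiteBindingClassifier(n_hidden=7, widths=[8] * 7, max_epochs=10, random_state=0)
        train_mask, val_mask = clf._split(X, y, groups, np.random.default_rng(0))
        val_groups = set(groups[val_mask])
        assert val_groups.isdisjoint(set(groups[train_mask]))

    def test_early_stopping_restores_best_epoch(self):
        rng = np.random.default_rng(6)
        X, y = _planted_table(rng, n=400)
        clf = SiteBindingClassifier(
            n_hidden=7, widths=[16] * 7, max_epochs=80, patience=6, random_state=1
        ).fit(X, y)
        hist = clf.history_["monitored_loss"]
        assert clf.history_["best_loss"] == pytest.approx(min(hist))

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        X, y = _planted_table(rng, n=200, d=12)
        clf = SiteBindingClassifier(n_hidden=7, widths=[8] * 7, max_epochs=10).fit(X, y)
        clf.save(tmp_path / "model")
        loaded = SiteBindingClassifier.load(tmp_path / "model")
        assert np.allclose(clf.predict_proba(X), loaded.predict_proba(X))


class TestClassWeightEquivalence:
    def test_weighting_matches_duplication(self):
        """Weighting the minority class by k matches duplicating it k times
        (one epoch, full-batch, fixed init, no dropout/batchnorm noise)."""
        from abdock.nn import MLPBinaryClassifier

        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 6))
        y = np.array([1] * 10 + [0] * 30)
        k = 3
        common = dict(widths=[8], dropout=0.0, batch_norm=False, lr=1e-2,
                      batch_size=10_000, max_epochs=1, patience=99, seed=3)
        m_w = MLPBinaryClassifier(**common)
        m_w.fit(X, y, class_weight={0: 1.0, 1: float(k)})
        X_dup = np.vstack([X, np.repeat(X[y == 1], k - 1, axis=0)])
        y_dup = np.concatenate([y, np.ones(10 * (k - 1), dtype=int)])
        m_d = MLPBinaryClassifier(**common)
        m_d.fit(X_dup, y_dup)
        assert np.allclose(m_w.predict_proba(X), m_d.predict_proba(X), atol=1e-6)


class TestEvaluateBinary:
    def test_perfect_separation(self):
        m = evaluate_binary([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m["roc_auc"] == 1.0 and m["pr_auc"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        m = evaluate_binary(rng.random(4000), y)
        assert abs(m["roc_auc"] - 0.5) < 0.05

    def test_four_point_hand_computed_roc(self):
        # probs 0.9(+), 0.7(-), 0.6(+), 0.2(-): ROC points give AUC = 3/4
        m = evaluate_binary([0.9, 0.7, 0.6, 0.2], [1, 0, 1, 0])
        assert m["roc_auc"] == pytest.approx(0.75)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(1.0)

    def test_youden_threshold(self):
        m = evaluate_binary([0.1, 0.35, 0.4, 0.8], [0, 0, 1, 1], youden=True)
        assert 0.35 < m["threshold"] <= 0.4
        assert m["recall"] == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_binary([0.5, 0.6], [1, 1])


class TestRandomSearchTuner:
    def test_returns_best_trial_and_refit(self):
        from abdock.site_predictors import tune_site_model

        rng = np.random.default_rng(0)
        X, y = _planted_table(rng, n=300, d=10)
        model, trials = tune_site_model(
            X, y, n_hidden=7, n_trials=3, random_state=1,
            max_epochs=15, patience=5,
        )
        assert len(trials) == 3
        assert all(0.0 <= t["val_roc_auc"] <= 1.0 for t in trials)
        assert model.predict_proba(X).shape == (300, 2)
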