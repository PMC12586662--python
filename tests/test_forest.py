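import numpy as np
import pytest
from scipy.special import expit

from ctgfusion import ForestHyper, ForestModel, fit_forest, oob_proba, predict_proba
from ctgfusion.forest import TreeArrays


def toy_data(rng, n=120):
    """Three well-separated Gaussian blobs in 4 dimensions."""
    X = np.vstack([
        rng.normal(0, 0.5, (n // 3, 4)),
        rng.normal(4, 0.5, (n // 3, 4)),
        rng.normal(8, 0.5, (n // 3, 4)),
    ])
    y = np.repeat([0, 1, 2], n // 3)
    return X, y


class TestFitForest:
    def test_separable_toy_training_accuracy(self, rng):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1],
                      [5, 5], [5, 6], [6, 5], [6, 6]], dtype=float)
        y = np.array([0, 0, 0, 0, 2, 2, 2, 2])
        model = fit_forest(X, y, ForestHyper(n_estimators=10, max_depth=3, seed=0))
        pred = model.classes_[predict_proba(model, X).argmax(axis=1)]
        assert np.mean(pred == y) == 1.0

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            fit_forest(X, np.zeros(10), ForestHyper())

    def test_nan_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[3, 1] = np.nan
        with pytest.raises(ValueError):
            fit_forest(X, np.repeat([0, 1], 5), ForestHyper())

    def test_deterministic_given_seed(self, rng):
        X, y = toy_data(rng)
        h = ForestHyper(n_estimators=5, seed=11)
        a = fit_forest(X, y, h)
        b = fit_forest(X, y, h)
        np.testing.assert_array_equal(predict_proba(a, X), predict_proba(b, X))
        for ba, bb in zip(a.bootstrap_indices, b.bootstrap_indices):
            np.testing.assert_array_equal(ba, bb)

    def test_hyper_validation(self):
        with pytest.raises(ValueError):
            ForestHyper(n_estimators=0)
        with pytest.raises(ValueError):
            ForestHyper(keep_proba=0.0)
        with pytest.raises(ValueError):
            ForestHyper(new_syn_data_frac=1.0)
        with pytest.raises(ValueError):
            ForestHyper(mode="boosted")


class TestPredictProba:
    def test_rows_sum_to_one(self, rng):
        X, y = toy_data(rng)
        for mode in ("deterministic", "probabilistic"):
            model = fit_forest(X, y, ForestHyper(n_estimators=8, mode=mode, seed=1))
            P = predict_proba(model, rng.normal(4, 3, (50, 4)))
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(P >= 0)

    def test_single_tree_forest_equals_its_tree(self, rng):
        X, y = toy_data(rng)
        model = fit_forest(X, y, ForestHyper(n_estimators=1, seed=2))
        P = predict_proba(model, X)
        np.testing.assert_allclose(P, model.trees[0].hard_leaf_distribution(X))

    def test_schema_mismatch_rejected(self, rng):
        X, y = toy_data(rng)
        model = fit_forest(X, y, ForestHyper(n_estimators=2, seed=0))
        with pytest.raises(ValueError):
            predict_proba(model, rng.normal(size=(5, 3)))

    def test_prf_degenerates_to_rf_exactly(self, rng):
        """keep_proba=1, zero softness, no augmentation => identical to the
        deterministic forest, tree for tree."""
        X, y = toy_data(rng)
        det = fit_forest(X, y, ForestHyper(n_estimators=10, seed=3))
        prf = fit_forest(X, y, ForestHyper(
            n_estimators=10, seed=3, mode="probabilistic",
            keep_proba=1.0, softness=0.0, new_syn_data_frac=0.0))
        Xq = rng.normal(4, 3, (40, 4))
        scale = prf.hyper.softness * prf.feature_mad
        for td, tp in zip(det.trees, prf.trees):
            np.testing.assert_array_equal(
                td.hard_leaf_distribution(Xq),
                tp.soft_distribution(Xq, scale, 1.0))
        np.testing.assert_array_equal(predict_proba(det, Xq),
                                      predict_proba(prf, Xq))


class TestSoftTraversal:
    def _hand_tree(self):
        """Depth-2 tree: root splits feature 0 at 0; children split feature 1
        at 1 and -1; four leaves with distinct class distributions."""
        return TreeArrays(
            feature=np.array([0, 1, 1, -2, -2, -2, -2]),
            threshold=np.array([0.0, 1.0, -1.0, 0, 0, 0, 0], dtype=float),
            left=np.array([1, 3, 5, -1, -1, -1, -1]),
            right=np.array([2, 4, 6, -1, -1, -1, -1]),
            value=np.array([
                [1 / 3, 1 / 3, 1 / 3], [0.5, 0.5, 0.0], [0.0, 0.5, 0.5],
                [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0], [0.5, 0.25, 0.25],
            ]),
        )

    def test_matches_exhaustive_path_enumeration(self):
        tree = self._hand_tree()
        scale = np.array([2.0, 1.5])
        x = np.array([[0.3, -0.4]])
        p_l = expit((0.0 - 0.3) / 2.0)
        p_ll = expit((1.0 - (-0.4)) / 1.5)
        p_rl = expit((-1.0 - (-0.4)) / 1.5)
        leaves = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0.5, 0.25, 0.25]])
        w = np.array([p_l * p_ll, p_l * (1 - p_ll),
                      (1 - p_l) * p_rl, (1 - p_l) * (1 - p_rl)])
        expected = (w[:, None] * leaves).sum(axis=0) / w.sum()
        got = tree.soft_distribution(x, scale, keep_proba=1e-9)[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_pruning_renormalizes_surviving_mass(self):
        tree = self._hand_tree()
        scale = np.array([2.0, 1.5])
        x = np.array([[3.0, 0.0]])  # right branch heavily favored
        full = tree.soft_distribution(x, scale, keep_proba=1e-9)[0]
        pruned = tree.soft_distribution(x, scale, keep_proba=0.3)[0]
        assert pruned.sum() == pytest.approx(1.0)
        assert not np.allclose(full, pruned)

    def test_all_paths_pruned_falls_back_to_hard_traversal(self):
        tree = self._hand_tree()
        scale = np.array([2.0, 1.5])
        x = np.array([[0.0, 0.0]])  # every path has probability ~0.25
        hard = tree.hard_leaf_distribution(x)
        soft = tree.soft_distribution(x, scale, keep_proba=0.99)
        np.testing.assert_allclose(soft, hard)


class TestOOB:
    def test_hand_built_bootstrap_bookkeeping(self, rng):
        X, y = toy_data(rng, n=12)
        model = fit_forest(X, y, ForestHyper(n_estimators=2, seed=7))
        model.bootstrap_indices = [
            np.array([0] * 6 + list(range(6, 12))),   # omits 1..5
            np.arange(12),                            # omits nothing
        ]
        est = oob_proba(model, X, y)
        omitted = np.arange(1, 6)
        np.testing.assert_allclose(
            est.proba[omitted],
            model.trees[0].hard_leaf_distribution(X[omitted]))
        assert est.covered[omitted].all()
        assert not est.covered[0]
        assert np.isnan(est.proba[0]).all()

    def test_requires_training_data(self, rng):
        X, y = toy_data(rng)
        model = fit_forest(X, y, ForestHyper(n_estimators=3, seed=1))
        with pytest.raises(ValueError):
            oob_proba(model, X + 1.0, y)

    def test_omission_fraction_near_bootstrap_limit(self, rng):
        """Per-tree OOB fraction approaches 1/e ~ 0.368 for n >= 100."""
        X, y = toy_data(rng, n=150)
        fracs = []
        for seed in range(10):
            model = fit_forest(X, y, ForestHyper(n_estimators=10, seed=seed))
            n = X.shape[0]
            for boot in model.bootstrap_indices:
                fracs.append(1.0 - np.unique(boot).size / n)
        assert 0.33 <= np.mean(fracs) <= 0.40

    def test_covered_rows_sum_to_one(self, rng):
        X, y = toy_data(rng)
        model = fit_forest(X, y, ForestHyper(n_estimators=10, seed=4,
                                             mode="probabilistic"))
        est = oob_proba(model, X, y)
        np.testing.assert_allclose(est.proba[est.covered].sum(axis=1), 1.0,
                                   atol=1e-9)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y = toy_data(rng)
        for mode in ("deterministic", "probabilistic"):
            model = fit_forest(X, y, ForestHyper(n_estimators=4, mode=mode, seed=5))
            path = tmp_path / f"{mode}.json"
            model.save(path)
            loaded = ForestModel.load(path)
            Xq = rng.normal(4, 2, (20, 4))
            np.testing.assert_array_equal(predict_proba(model, Xq),
                                          predict_proba(loaded, Xq))
            assert loaded.training_checksum == model.training_checksum
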