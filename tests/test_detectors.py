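import numpy as np
import pytest
from sklearn.svm import SVC

from szdet.detectors import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    LineLengthDetector,
    LineLengthModel,
    RandomForestDetector,
    Tree,
    default_mtry,
    forest_from_json,
    forest_to_json,
    fuse_channels,
    gini_impurity,
    gini_impurity_decrease,
    ll_block_stats,
    ll_score,
    rbf_kernel_value,
    rf_score,
    rf_train,
    svm_decision_expansion,
    svm_score,
    svm_train,
)
from szdet.errors import DegenerateDataError, InvalidInputError
from szdet.evaluation import roc_auc


# --- independent oracles ---------------------------------------------------


def gini_decrease_oracle(parent, left, right):
    def g(counts):
        n = sum(counts)
        return 1.0 - sum((c / n) ** 2 for c in counts)

    n, nl, nr = sum(parent), sum(left), sum(right)
    gl = g(left) if nl else 0.0
    gr = g(right) if nr else 0.0
    return g(parent) - nl / n * gl - nr / n * gr


def best_stump_oracle(x, y):
    """Exhaustive best (threshold, gain) for a 1-D split."""
    xs = np.unique(x)
    best_gain, best_thr = -1.0, None
    for lo, hi in zip(xs[:-1], xs[1:]):
        thr = (lo + hi) / 2
        left = y[x <= thr]
        right = y[x > thr]
        gain = gini_decrease_oracle(
            [int((y == 0).sum()), int((y == 1).sum())],
            [int((left == 0).sum()), int((left == 1).sum())],
            [int((right == 0).sum()), int((right == 1).sum())],
        )
        if gain > best_gain + 1e-12:
            best_gain, best_thr = gain, thr
    return best_thr, best_gain


class TestLineLength:
    def test_mean_epoch_scores_zero(self, rng):
        ll = rng.standard_normal(100) + 10
        model = ll_block_stats(ll)
        assert ll_score(np.array([model.mean]), model)[0] == 0.0

    def test_scores_are_zscores(self, rng):
        ll = rng.standard_normal(500) * 3 + 7
        z = ll_score(ll, ll_block_stats(ll))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_roc_invariant_under_zscoring(self, rng):
        ll = rng.standard_normal(300)
        labels = rng.random(300) < 0.3
        _, auc_raw = roc_auc(ll, labels)
        _, auc_z = roc_auc(ll_score(ll, ll_block_stats(ll)), labels)
        assert auc_raw == pytest.approx(auc_z, abs=1e-12)

    def test_zero_std_rejected(self):
        with pytest.raises(DegenerateDataError):
            ll_block_stats(np.full(10, 2.0))

    def test_masked_epochs_excluded_from_stats(self, rng):
        ll = rng.standard_normal(100)
        mask = np.zeros(100, dtype=bool)
        mask[:10] = True
        model = ll_block_stats(ll, mask)
        assert model.mean == pytest.approx(ll[10:].mean())


class TestGini:
    def test_pure_parent_zero(self):
        assert gini_impurity([7, 0]) == 0.0
        assert gini_impurity_decrease([7, 0], [3, 0], [4, 0]) == 0.0

    def test_perfect_split_half(self):
        assert gini_impurity_decrease([5, 5], [5, 0], [0, 5]) == pytest.approx(0.5)

    def test_random_counts_match_oracle(self, rng):
        for _ in range(100):
            left = rng.integers(0, 20, size=2)
            right = rng.integers(0, 20, size=2)
            if left.sum() + right.sum() == 0:
                continue
            parent = left + right
            assert gini_impurity_decrease(parent, left, right) == pytest.approx(
                gini_decrease_oracle(parent.tolist(), left.tolist(), right.tolist())
            )

    def test_empty_parent_rejected(self):
        with pytest.raises(InvalidInputError):
            gini_impurity([])

    def test_mismatched_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            gini_impurity_decrease([4, 4], [1, 1], [1, 1])


class TestRandomForest:
    def test_default_mtry_is_four_for_ten_features(self):
        assert default_mtry(10) == 4
        x = np.random.default_rng(0).standard_normal((40, 10))
        y = (x[:, 0] > 0).astype(int)
        assert rf_train(x, y, n_trees=5, seed=0).mtry == 4

    def test_separable_toy_set(self, rng):
        x = rng.standard_normal((60, 10))
        y = (x[:, 3] > 0).astype(int)
        x[:, 3] += np.where(y == 1, 5.0, -5.0)  # make feature 3 perfectly separating
        forest = rf_train(x, y, n_trees=20, mtry=10, seed=1)
        votes = rf_score(forest, x)
        np.testing.assert_array_equal(votes[y == 1], 1.0)
        np.testing.assert_array_equal(votes[y == 0], 0.0)

    def test_stump_matches_exhaustive_split_search(self, rng):
        # single tree, mtry = all features, 1-D data, grown one level
        for _ in range(25):
            x = rng.standard_normal((4, 1))
            y = np.array([0, 0, 1, 1], dtype=np.int8)
            if np.unique(x).size < 4:
                continue
            from szdet.detectors import _grow_tree

            tree = _grow_tree(x, y, mtry=1, min_samples_split=2, rng=np.random.default_rng(0))
            thr_oracle, gain_oracle = best_stump_oracle(x[:, 0], y)
            if gain_oracle <= 0:
                continue
            root_thr = tree.threshold[0]
            # the root split must equal the exhaustive optimum
            left_o = y[x[:, 0] <= thr_oracle]
            left_t = y[x[:, 0] <= root_thr]
            gain_tree = gini_decrease_oracle(
                [2, 2],
                [int((left_t == 0).sum()), int((left_t == 1).sum())],
                [int((y[x[:, 0] > root_thr] == 0).sum()), int((y[x[:, 0] > root_thr] == 1).sum())],
            )
            assert gain_tree == pytest.approx(gain_oracle, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        x = rng.standard_normal((80, 10))
        y = (x[:, 0] + 0.5 * rng.standard_normal(80) > 0).astype(int)
        a = rf_train(x, y, n_trees=10, seed=3)
        b = rf_train(x, y, n_trees=10, seed=3)
        probe = rng.standard_normal((30, 10))
        np.testing.assert_array_equal(rf_score(a, probe), rf_score(b, probe))

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((20, 10))
        with pytest.raises(InvalidInputError):
            rf_train(x, np.zeros(20, dtype=int))

    def test_oob_fraction_near_e_inverse(self, rng):
        # bootstrap leaves ~e^-1 of rows out of each tree's sample
        n = 500
        out_fracs = []
        gen = np.random.default_rng(0)
        for _ in range(200):
            boot = gen.integers(0, n, size=n)
            out_fracs.append(1 - np.unique(boot).size / n)
        assert np.mean(out_fracs) == pytest.approx(np.exp(-1), abs=0.01)

    def test_vote_fraction_is_mean_of_tree_predictions(self, rng):
        x = rng.standard_normal((100, 10))
        y = (x[:, 1] > 0).astype(int)
        forest = rf_train(x, y, n_trees=15, seed=2)
        probe = rng.standard_normal((40, 10))
        per_tree = np.stack([t.predict(probe) for t in forest.trees])
        np.testing.assert_allclose(rf_score(forest, probe), per_tree.mean(axis=0))

    def test_degenerate_all_seizure_forest_scores_one(self):
        leaf = Tree(
            feature=np.array([-1], dtype=np.int16),
            threshold=np.array([0.0]),
            left=np.array([0], dtype=np.int32),
            right=np.array([0], dtype=np.int32),
            leaf_label=np.array([1], dtype=np.int8),
        )
        from szdet.detectors import ForestModel

        forest = ForestModel(trees=[leaf] * 10, mtry=4, n_features=10, oob_error=0.0, seed=0)
        assert rf_score(forest, np.zeros((3, 10)))[0] == 1.0

    def test_vote_counting(self, rng):
        pos = Tree(
            feature=np.array([-1], dtype=np.int16),
            threshold=np.array([0.0]),
            left=np.array([0], dtype=np.int32),
            right=np.array([0], dtype=np.int32),
            leaf_label=np.array([1], dtype=np.int8),
        )
        neg = Tree(
            feature=np.array([-1], dtype=np.int16),
            threshold=np.array([0.0]),
            left=np.array([0], dtype=np.int32),
            right=np.array([0], dtype=np.int32),
            leaf_label=np.array([0], dtype=np.int8),
        )
        from szdet.detectors import ForestModel

        forest = ForestModel(
            trees=[pos] * 40 + [neg] * 60, mtry=4, n_features=10, oob_error=0.0, seed=0
        )
        assert rf_score(forest, np.zeros((1, 10)))[0] == pytest.approx(0.40)

    def test_json_roundtrip(self, rng, tmp_path):
        x = rng.standard_normal((60, 10))
        y = (x[:, 0] > 0).astype(int)
        forest = rf_train(x, y, n_trees=5, seed=0)
        path = tmp_path / "forest.json"
        forest_to_json(forest, path)
        back = forest_from_json(path)
        probe = rng.standard_normal((20, 10))
        np.testing.assert_array_equal(rf_score(forest, probe), rf_score(back, probe))


class TestSvm:
    def test_kernel_at_zero_distance(self, rng):
        for _ in range(10):
            x = rng.standard_normal(10)
            assert rbf_kernel_value(x, x, gamma=rng.uniform(0.01, 10)) == 1.0

    def test_default_grids_match_convention(self):
        assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-15 and DEFAULT_GAMMA_GRID[-1] == 2.0**3

    @pytest.fixture
    def clouds(self, rng):
        n = 60
        x = np.vstack(
            [rng.standard_normal((n, 4)) + 4.0, rng.standard_normal((n, 4)) - 4.0]
        )
        y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
        return x, y

    def test_separated_clouds_learned(self, clouds, rng):
        x, y = clouds
        model = svm_train(x, y, c_grid=(1.0, 16.0), gamma_grid=(0.01, 0.1), seed=0)
        assert model.cv_accuracy > 0.99
        held = np.vstack([rng.standard_normal((10, 4)) + 4.0, rng.standard_normal((10, 4)) - 4.0])
        values = svm_score(model, held)
        assert (values[:10] > 0).all() and (values[10:] < 0).all()

    def test_decision_matches_kernel_expansion(self, clouds, rng):
        x, y = clouds
        model = svm_train(x, y, c_grid=(4.0,), gamma_grid=(0.05,), seed=0)
        for probe in rng.standard_normal((5, 4)) * 3:
            expansion = svm_decision_expansion(model, probe)
            assert svm_score(model, probe)[0] == pytest.approx(expansion, rel=1e-8, abs=1e-10)

    def test_support_vector_margin(self, clouds):
        x, y = clouds
        model = svm_train(x, y, c_grid=(1e4,), gamma_grid=(0.05,), seed=0)
        sv_values = model.svc.decision_function(model.svc.support_vectors_)
        assert (np.abs(sv_values) >= 1 - 1e-3).all()

    def test_symmetric_midpoint_scores_zero(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, 0])
        model = svm_train(x, y, c_grid=(10.0,), gamma_grid=(0.5,), seed=0)
        assert svm_score(model, np.array([0.0, 0.0]))[0] == pytest.approx(0.0, abs=1e-9)

    def test_small_gamma_limit_matches_linear_svm(self, rng):
        # six separable points; as gamma -> 0 the RBF boundary -> linear
        x = np.array([[2.0, 1], [3, 2], [2.5, 0], [-2, -1], [-3, -2], [-2.5, 0]])
        y = np.array([1, 1, 1, 0, 0, 0])
        gamma = 1e-4
        model = svm_train(x, y, c_grid=(1e6,), gamma_grid=(gamma,), seed=0)
        lin = SVC(kernel="linear", C=1e6).fit(model.normalize(x), y)
        probes = rng.standard_normal((50, 2)) * 2
        rbf_pred = svm_score(model, probes) > 0
        lin_pred = lin.decision_function(model.normalize(probes)) > 0
        assert (rbf_pred == lin_pred).mean() >= 0.95

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            svm_train(rng.standard_normal((10, 3)), np.ones(10, dtype=int))

    def test_empty_grid_rejected(self, clouds):
        x, y = clouds
        with pytest.raises(InvalidInputError):
            svm_train(x, y, c_grid=(), gamma_grid=(0.1,))


class TestFusion:
    def test_or_semantics(self):
        det = np.array([[0, 0, 1, 0], [0, 1, 0, 0]], dtype=bool)
        np.testing.assert_array_equal(fuse_channels(det, "or"), [False, True, True, False])

    def test_all_negative(self):
        assert not fuse_channels(np.zeros((3, 5), dtype=bool), "or").any()

    def test_max_score_thresholding_equals_or(self, rng):
        scores = rng.standard_normal((4, 200))
        for t in (-0.5, 0.0, 1.0):
            fused = fuse_channels(scores, "max") > t
            orred = fuse_channels(scores > t, "or")
            np.testing.assert_array_equal(fused, orred)

    def test_unknown_mode(self):
        with pytest.raises(InvalidInputError):
            fuse_channels(np.zeros((2, 3)), "sum")


class TestDetectorApi:
    def test_detectors_score_synthetic_blocks_above_chance(self, small_lvfa_blocks):
        from szdet.evaluation import evaluate_loso

        for factory in (
            LineLengthDetector,
            lambda: RandomForestDetector(n_trees=30, seed=0),
        ):
            rep = evaluate_loso(small_lvfa_blocks, factory, channels=[0])
            assert rep.auc > 0.5
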