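import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from responsekit.datatypes import AnalysisConfig
from responsekit.models import (
    auc,
    class_balance_weights,
    evaluate_multisplit,
    grid_search_lssvm,
    train_rf,
    train_weighted_lssvm,
)


def enumerate_auc(scores, labels):
    """Oracle: exhaustive pairwise enumeration with ties counted 0.5."""
    pos = [s for s, l in zip(scores, labels) if l > 0]
    neg = [s for s, l in zip(scores, labels) if l <= 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1]) == 1.0

    def test_tied_pair_counts_half(self):
        # 4 pairs: 3 concordant + 1 tie -> 3.5/4
        assert auc([0.9, 0.8, 0.8, 0.1], [1, 1, -1, -1]) == 0.875

    def test_reversal_antisymmetry(self, rng):
        s = rng.random(20)
        y = np.where(rng.random(20) < 0.5, 1, -1)
        y[0], y[1] = 1, -1  # both classes
        assert auc(-s, y) == pytest.approx(1.0 - auc(s, y))

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="one class"):
            auc([0.1, 0.2], [1, 1])

    def test_matches_enumeration_exhaustively(self):
        alphabet = (0.2, 0.5, 0.8)
        for n in (2, 3, 4, 5):
            for scores in itertools.product(alphabet, repeat=n):
                for k in range(1, n):
                    labels = [1] * k + [-1] * (n - k)
                    assert auc(np.array(scores), np.array(labels)) == (
                        pytest.approx(enumerate_auc(scores, labels))
                    )

    def test_matches_sklearn_on_random_vectors(self, rng):
        for _ in range(50):
            s = rng.choice([0.1, 0.3, 0.5, 0.7], size=12)
            y = np.where(rng.random(12) < 0.5, 1, -1)
            y[:2] = [1, -1]
            assert auc(s, y) == pytest.approx(
                roc_auc_score((y > 0).astype(int), s)
            )

    @given(
        st.lists(
            st.floats(-5, 5).map(lambda v: round(v, 3)),
            min_size=4, max_size=12,
        ),
        st.floats(0.1, 3.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, scores, scale):
        scores = np.array(scores)
        n = len(scores)
        y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
        transformed = np.exp(scale * scores)  # strictly monotone
        assert auc(scores, y) == pytest.approx(auc(transformed, y))


class TestWeightedLssvm:
    def test_two_point_hand_solution(self):
        """1-D, x=(-1,+1), y=(-1,+1), gamma=1, equal weights."""
        m = train_weighted_lssvm(
            np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]),
            gamma=1.0, weights=np.ones(2), calibrate=False,
        )
        assert m.b == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(m.alpha, [-1 / 3, 1 / 3], atol=1e-12)
        x = np.array([[0.5], [2.0]])
        np.testing.assert_allclose(
            m.decision_function(x), (2 / 3) * x.ravel(), atol=1e-12
        )

    def test_balanced_classes_have_unit_weights(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        np.testing.assert_allclose(class_balance_weights(y), np.ones(4))

    def test_imbalanced_weights_formula(self):
        y = np.array([1.0, -1.0, -1.0, -1.0])
        np.testing.assert_allclose(
            class_balance_weights(y), [2.0, 2 / 3, 2 / 3, 2 / 3]
        )

    def test_duplicated_training_set_same_decision_function(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.where(rng.random(10) < 0.5, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        w = class_balance_weights(y)
        m1 = train_weighted_lssvm(X, y, gamma=2.0, weights=w, calibrate=False)
        # duplicating every sample halves the effective per-sample penalty
        # 1/(gamma*w); doubling gamma on the duplicated set restores it
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        m2 = train_weighted_lssvm(
            X2, y2, gamma=1.0, weights=np.concatenate([w, w]),
            calibrate=False,
        )
        T = rng.standard_normal((5, 3))
        np.testing.assert_allclose(
            m1.decision_function(T), m2.decision_function(T), atol=1e-8
        )

    @pytest.mark.parametrize("kernel", ["linear", "radial"])
    def test_matches_dense_solver_oracle(self, kernel, rng):
        """Dual solution reproduces an lstsq solve of the saddle system."""
        from responsekit.models import _kernel_matrix

        for _ in range(25):
            n = int(rng.integers(4, 31))
            p = int(rng.integers(1, 6))
            X = rng.standard_normal((n, p))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            y[:2] = [1.0, -1.0]
            gamma = float(rng.uniform(0.1, 10))
            m = train_weighted_lssvm(X, y, gamma=gamma, kernel=kernel,
                                     calibrate=False)
            K = _kernel_matrix(X, X, kernel, None)
            A = np.zeros((n + 1, n + 1))
            A[0, 1:] = 1.0
            A[1:, 0] = 1.0
            A[1:, 1:] = K + np.diag(1.0 / (gamma * m.weights))
            sol, *_ = np.linalg.lstsq(A, np.concatenate(([0.0], y)),
                                      rcond=None)
            rel = np.linalg.norm(
                np.concatenate(([m.b], m.alpha)) - sol
            ) / np.linalg.norm(sol)
            assert rel <= 1e-8

    def test_alpha_sums_to_zero(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 20))
            X = rng.standard_normal((n, 4))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            y[:2] = [1.0, -1.0]
            m = train_weighted_lssvm(X, y, gamma=1.0, calibrate=False)
            assert abs(m.alpha.sum()) < 1e-8

    def test_system_residual(self, rng):
        """(alpha, b) satisfy the weighted saddle system to 1e-8."""
        from responsekit.models import _kernel_matrix

        X = rng.standard_normal((15, 3))
        y = np.where(np.arange(15) < 7, 1.0, -1.0)
        m = train_weighted_lssvm(X, y, gamma=5.0, calibrate=False)
        K = _kernel_matrix(X, X, "linear", None)
        resid = K @ m.alpha + m.alpha / (5.0 * m.weights) + m.b - y
        assert np.linalg.norm(resid) / np.linalg.norm(y) < 1e-8
        assert abs(m.alpha.sum()) < 1e-8

    def test_calibrated_probabilities_ordered(self, rng):
        X = rng.standard_normal((20, 2))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        m = train_weighted_lssvm(X, y, gamma=1.0)
        p = m.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        assert p[y > 0].mean() > p[y < 0].mean()


class TestGridSearch:
    def test_single_cell_returned_unchanged(self, rng):
        X = rng.standard_normal((20, 30))
        y = np.where(np.arange(20) < 10, 1.0, -1.0)
        gs = grid_search_lssvm(X, y, k_grid=(7,), gamma_grid=(3.0,), seed=0)
        assert gs.k == 7 and gs.gamma == 3.0

    def test_planted_feature_recovery(self, rng):
        """10 planted of 1000, effect 1.5 SD, n=40: small k, most recovered."""
        n, p, n_true = 40, 1000, 10
        y = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        X = rng.standard_normal((n, p))
        X[:, :n_true] += 1.5 * (y[:, None] > 0)
        gs = grid_search_lssvm(X, y, seed=1)
        assert gs.k <= 50
        top = set(gs.ranked_features[: gs.k])
        assert len(top & set(range(n_true))) >= 8

    def test_permuted_labels_give_chance_inner_auc(self, rng):
        n, p = 40, 200
        X = rng.standard_normal((n, p))
        aucs = []
        for rep in range(20):
            y = np.where(rng.permutation(n) < n // 2, 1.0, -1.0)
            gs = grid_search_lssvm(X, y, k_grid=(25,), gamma_grid=(1.0,),
                                   seed=rep)
            aucs.append(gs.mean_inner_auc)
        # selection over a single cell: unbiased null, chance level
        assert abs(np.mean(aucs) - 0.5) < 0.15


class TestRandomForest:
    def test_separable_points_fit(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1.0, 1.0])
        rf = train_rf(X, y, n_trees=1, seed=0)
        assert (rf.predict(X) == [0, 1]).all()

    def test_same_seed_identical(self, rng):
        X = rng.standard_normal((30, 10))
        y = np.where(X[:, 0] + 0.5 * rng.standard_normal(30) > 0, 1.0, -1.0)
        y[:2] = [1.0, -1.0]
        p1 = train_rf(X, y, n_trees=50, seed=3).predict_proba(X)
        p2 = train_rf(X, y, n_trees=50, seed=3).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_planted_features_dominate_importances(self, rng):
        n, p, n_true = 48, 300, 15
        y = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        X = rng.standard_normal((n, p))
        X[:, :n_true] += 1.5 * (y[:, None] > 0)
        rf = train_rf(X, y, n_trees=300, seed=0)
        top20 = np.argsort(-rf.feature_importances_)[:20]
        assert np.isin(top20, np.arange(n_true)).sum() >= 10


class TestMultisplit:
    CFG = AnalysisConfig(k_grid=(25, 50), gamma_grid=(1.0,), inner_folds=3)

    def test_separable_signal_single_split(self, rng):
        n = 24
        y = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        X = rng.standard_normal((n, 30))
        X[:, 0] += 10.0 * (y > 0)
        ev = evaluate_multisplit(X, y, n_splits=1, seed=0, config=self.CFG)
        assert ev.per_split_auc == [1.0]

    def test_null_labels_give_chance_auc(self, rng):
        n = 48
        X = rng.standard_normal((n, 100))
        y = np.where(rng.permutation(n) < n // 2, 1.0, -1.0)
        ev = evaluate_multisplit(X, y, n_splits=40, seed=1, config=self.CFG)
        assert 0.4 <= ev.mean_auc <= 0.6

    def test_stratified_split_shapes(self, rng):
        n = 48
        y = np.where(np.arange(n) < 20, 1.0, -1.0)
        X = rng.standard_normal((n, 10))
        ev = evaluate_multisplit(X, y, n_splits=5, seed=0, config=self.CFG,
                                 select_features=False)
        for tr, te in ev.splits:
            assert len(tr) + len(te) == n
            assert abs(len(tr) / n - 2 / 3) < 0.05
            assert len(np.unique(y[te])) == 2

    def test_rf_route(self, rng):
        n = 30
        y = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        X = rng.standard_normal((n, 20))
        X[:, 0] += 3.0 * (y > 0)
        cfg = self.CFG.with_updates(n_trees=100)
        ev = evaluate_multisplit(X, y, method="rf", n_splits=5, seed=0,
                                 config=cfg)
        assert ev.mean_auc > 0.8

    def test_minimum_size_contracts(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="6 labeled"):
            evaluate_multisplit(X, np.array([1.0, 1.0, -1.0, -1.0]))
        X = rng.standard_normal((8, 3))
        y = np.array([1.0] + [-1.0] * 7)
        with pytest.raises(ValueError, match="2 lines per class"):
            evaluate_multisplit(X, y)

    def test_test_fold_never_drives_feature_selection(self, rng):
        """A feature informative only on test lines must not be selected.

        Canary for label leakage: the feature below is pure noise on every
        possible training subset statistic unless test labels leak into the
        ranking.
        """
        n = 30
        y = np.where(np.arange(n) < n // 2, 1.0, -1.0)
        X = rng.standard_normal((n, 60))
        from sklearn.model_selection import StratifiedShuffleSplit

        sss = StratifiedShuffleSplit(n_splits=8, train_size=2 / 3,
                                     random_state=0)
        hits = 0
        total = 0
        for tr, te in sss.split(X, y):
            Xc = X.copy()
            Xc[te, 0] = 100.0 * y[te]  # perfect on test rows only
            gs = grid_search_lssvm(Xc[tr], y[tr], k_grid=(5,),
                                   gamma_grid=(1.0,), seed=0)
            hits += 0 in gs.ranked_features[:5]
            total += 1
        # 0 should be selected no more often than any noise feature
        assert hits <= 2
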