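"""Exact Shapley attribution: brute-force oracle and tree algorithm agreement."""

import numpy as np
import pytest

from shapdrift.shapley import (
    BackgroundSet,
    TreeExplainer,
    brute_force_shapley,
    explain_cohort,
    probability_view,
    tree_shapley,
)
from shapdrift.trees import LEAF, Tree, TreeEnsemble

from conftest import random_ensemble


def and_tree():
    """Leaf value 1 iff x0 > 0.5 and x1 > 0.5, else 0."""
    return Tree(
        feature=[0, LEAF, 1, LEAF, LEAF],
        threshold=[0.5, 0, 0.5, 0, 0],
        left=[1, 0, 3, 0, 0],
        right=[2, 0, 4, 0, 0],
        default_left=[True, False, True, False, False],
        value=[0, 0, 0, 0, 1.0],
    )


@pytest.fixture
def corners_background():
    return BackgroundSet(np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float))


class TestBruteForce:
    def test_single_feature_game(self):
        ens = TreeEnsemble([and_tree()], 0.0, ["a", "b"])
        # d=1 via a stump on one feature
        stump = Tree([0, LEAF, LEAF], [0.0, 0, 0], [1, 0, 0], [2, 0, 0], [False] * 3, [0, -1.0, 1.0])
        e1 = TreeEnsemble([stump], 0.0, ["a"])
        bg = BackgroundSet(np.array([[-1.0], [1.0]]))
        attr = brute_force_shapley(e1.predict_margin, np.array([2.0]), bg)
        # phi1 = f(x) - mean_bg f = 1 - 0 = 1
        assert attr.phi[0, 0] == pytest.approx(1.0)
        assert attr.phi0 == pytest.approx(0.0)

    def test_and_game_hand_values(self, corners_background):
        ens = TreeEnsemble([and_tree()], 0.0, ["a", "b"])
        attr = brute_force_shapley(ens.predict_margin, np.array([1.0, 1.0]), corners_background)
        assert attr.phi0 == pytest.approx(0.25)
        np.testing.assert_allclose(attr.phi[0], [0.375, 0.375], atol=1e-12)

    def test_symmetry_axiom(self, corners_background):
        ens = TreeEnsemble([and_tree()], 0.0, ["a", "b"])
        attr = brute_force_shapley(ens.predict_margin, np.array([1.0, 1.0]), corners_background)
        assert attr.phi[0, 0] == pytest.approx(attr.phi[0, 1], abs=1e-12)

    def test_feature_count_contract(self):
        with pytest.raises(ValueError):
            brute_force_shapley(lambda X: X.sum(1), np.zeros(16), BackgroundSet(np.zeros((1, 16))))


class TestTreeShapley:
    def test_matches_hand_and_game(self, corners_background):
        ens = TreeEnsemble([and_tree()], 0.0, ["a", "b"])
        attr = tree_shapley(ens, np.array([1.0, 1.0]), corners_background)
        np.testing.assert_allclose(attr.phi[0], [0.375, 0.375], atol=1e-12)
        assert attr.phi0 == pytest.approx(0.25)

    def test_additive_ensemble_closed_form(self):
        """f(x) = f1(x0) + f2(x1): phi_i = mean_bg[f_i(x_i) - f_i(Z_i)]."""
        s0 = Tree([0, LEAF, LEAF], [0.0, 0, 0], [1, 0, 0], [2, 0, 0], [False] * 3, [0, -1.0, 2.0])
        s1 = Tree([1, LEAF, LEAF], [1.0, 0, 0], [1, 0, 0], [2, 0, 0], [False] * 3, [0, 0.5, -0.5])
        ens = TreeEnsemble([s0, s1], 0.0, ["a", "b"])
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(16, 2))
        bg = BackgroundSet(Z)
        x = np.array([1.5, -0.5])
        attr = tree_shapley(ens, x, bg)
        e0 = TreeEnsemble([s0], 0.0, ["a", "b"])
        e1 = TreeEnsemble([s1], 0.0, ["a", "b"])
        expect0 = e0.predict_margin(x[None]) - e0.predict_margin(Z).mean()
        expect1 = e1.predict_margin(x[None]) - e1.predict_margin(Z).mean()
        assert attr.phi[0, 0] == pytest.approx(expect0[0], abs=1e-12)
        assert attr.phi[0, 1] == pytest.approx(expect1[0], abs=1e-12)

    def test_dummy_feature_gets_exact_zero(self, rng):
        ens, X = random_ensemble(rng, d=4, n_trees=8)
        # append an unused column
        wide = np.hstack([X[:5], rng.normal(size=(5, 1))])
        ens_wide = TreeEnsemble(ens.trees, ens.base_score, ens.feature_names + ["unused"])
        bg = BackgroundSet(wide)
        attr = TreeExplainer(ens_wide, bg).shap_values(wide)
        np.testing.assert_array_equal(attr.phi[:, -1], 0.0)

    def test_oracle_equivalence_random_ensembles(self, rng):
        """Tree algorithm equals coalition enumeration to 1e-8."""
        for _ in range(6):
            d = int(rng.integers(2, 8))
            ens, X = random_ensemble(rng, d=d, n_trees=int(rng.integers(2, 12)))
            bg = BackgroundSet(X[rng.integers(0, len(X), size=6)])
            x = X[int(rng.integers(0, len(X)))]
            fast = tree_shapley(ens, x, bg)
            slow = brute_force_shapley(ens.predict_margin, x, bg)
            np.testing.assert_allclose(fast.phi[0], slow.phi[0], atol=1e-8)
            assert fast.phi0 == pytest.approx(slow.phi0, abs=1e-8)

    def test_attributions_additive_across_trees(self, rng):
        ens, X = random_ensemble(rng, d=5, n_trees=6)
        bg = BackgroundSet(X[:10])
        x = X[40]
        whole = tree_shapley(ens, x, bg).phi[0]
        parts = np.zeros_like(whole)
        for tree in ens.trees:
            sub = TreeEnsemble([tree], 0.0, ens.feature_names)
            parts += tree_shapley(sub, x, bg).phi[0]
        np.testing.assert_allclose(whole, parts, atol=1e-10)

    def test_schema_mismatch_raises(self, rng):
        ens, X = random_ensemble(rng, d=4)
        with pytest.raises(ValueError):
            TreeExplainer(ens, BackgroundSet(np.zeros((3, 5))))


class TestExplainCohort:
    def test_single_row_matches_tree_shapley(self, rng):
        ens, X = random_ensemble(rng, d=5)
        bg = BackgroundSet(X[:8])
        single = explain_cohort(ens, X[10:11], bg)
        direct = tree_shapley(ens, X[10], bg)
        np.testing.assert_allclose(single.phi, direct.phi, atol=1e-12)

    def test_duplicated_rows_get_identical_attributions(self, rng):
        ens, X = random_ensemble(rng, d=5)
        bg = BackgroundSet(X[:8])
        dup = np.vstack([X[3], X[3]])
        attr = explain_cohort(ens, dup, bg)
        np.testing.assert_array_equal(attr.phi[0], attr.phi[1])

    def test_local_accuracy_on_cohort(self, fitted_small):
        X, ens, bg = fitted_small
        attr = explain_cohort(ens, X.frame.head(200).to_numpy(), bg)
        assert attr.local_accuracy_error().max() < 1e-8

    def test_row_order_preserved_and_ids_carried(self, rng):
        ens, X = random_ensemble(rng, d=4)
        bg = BackgroundSet(X[:6])
        ids = np.array([f"E{i}" for i in range(10)])
        attr = explain_cohort(ens, X[:10], bg, episode_ids=ids)
        np.testing.assert_array_equal(attr.episode_ids, ids)
        frame = attr.to_frame()
        assert list(frame["episode_id"]) == list(ids)

    def test_empty_cohort_rejected(self, rng):
        ens, X = random_ensemble(rng, d=4)
        with pytest.raises(ValueError):
            explain_cohort(ens, X[:0], BackgroundSet(X[:4]))


class TestProbabilityView:
    def test_local_accuracy_on_probability_scale(self, rng):
        ens, X = random_ensemble(rng, d=5)
        bg = BackgroundSet(X[:8])
        attr = explain_cohort(ens, X[:20], bg)
        prob = probability_view(attr)
        sig = lambda z: 1 / (1 + np.exp(-z))
        np.testing.assert_allclose(
            prob.phi0 + prob.phi.sum(1), sig(attr.margins), atol=1e-10
        )

    def test_rescaling_preserves_shares(self, rng):
        from shapdrift.driftstats import normalise_attributions

        ens, X = random_ensemble(rng, d=5)
        bg = BackgroundSet(X[:8])
        attr = explain_cohort(ens, X[:20], bg)
        s_margin = normalise_attributions(attr).shares
        s_prob = normalise_attributions(probability_view(attr)).shares
        np.testing.assert_allclose(s_margin, s_prob, atol=1e-12)
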