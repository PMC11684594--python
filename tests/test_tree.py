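"""Honest causal tree: halves, structure search, honest estimation, routing."""

import numpy as np
import pandas as pd
import pytest

import drcate as dc
from drcate.tree import (
    TreeNode,
    estimate_leaves,
    grow_tree,
    leaf_membership,
    predict_cate,
    predict_cate_batch,
    split_honest_halves,
)


def brute_force_root_split(Xmat, y, w, rows, min_leaf, statistic="effect_score"):
    """Independent exhaustive search over every (feature, midpoint) pair."""
    best = None
    for f in range(Xmat.shape[1]):
        vals = np.unique(Xmat[rows, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            mask = Xmat[rows, f] <= thr
            L, R = rows[mask], rows[~mask]
            if any(
                min((w[I] == 1).sum(), (w[I] == 0).sum()) < min_leaf for I in (L, R)
            ):
                continue
            if statistic == "effect_score":
                crit = len(L) * y[L].mean() ** 2 + len(R) * y[R].mean() ** 2
            else:
                tL = y[L][w[L] == 1].mean() - y[L][w[L] == 0].mean()
                tR = y[R][w[R] == 1].mean() - y[R][w[R] == 0].mean()
                crit = len(L) * tL**2 + len(R) * tR**2
            if best is None or crit > best[0] + 1e-12:
                best = (crit, f, thr)
    return best


class TestHonestHalves:
    def test_stratified_counts(self):
        W = np.array([1] * 40 + [0] * 60)
        s, e = split_honest_halves(100, W, seed=0)
        assert W[s].sum() == 20 and W[e].sum() == 20
        assert len(s) == 50 and len(e) == 50

    def test_deterministic_and_partition(self):
        W = np.array([0, 1] * 25 + [0])
        s1, e1 = split_honest_halves(51, W, seed=5)
        s2, e2 = split_honest_halves(51, W, seed=5)
        assert np.array_equal(s1, s2) and np.array_equal(e1, e2)
        assert len(np.intersect1d(s1, e1)) == 0
        assert np.array_equal(np.sort(np.concatenate([s1, e1])), np.arange(51))

    def test_tiny_arm_rejected(self):
        with pytest.raises(ValueError):
            split_honest_halves(3, np.array([1, 0, 0]), seed=0)


class TestGrowTree:
    def test_min_leaf_equal_to_n_gives_single_leaf(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 5, size=(60, 2)).astype(float)
        W = np.tile([0, 1], 30)
        D = rng.normal(size=60)
        root = grow_tree(X, W, D, np.arange(60), min_leaf=60, max_depth=3)
        assert root.is_leaf

    def test_constant_outcome_gives_single_leaf(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 8, size=(80, 3)).astype(float)
        W = np.tile([0, 1], 40)
        root = grow_tree(X, W, np.full(80, 2.0), np.arange(80), min_leaf=5, max_depth=3)
        assert root.is_leaf

    @pytest.mark.parametrize("seed", range(8))
    def test_root_split_matches_exhaustive_oracle(self, seed):
        """Greedy root split == brute force on small n, d <= 3."""
        rng = np.random.default_rng(seed)
        n = 120 + 10 * seed
        X = rng.integers(1, 10, size=(n, 3)).astype(float)
        W = (rng.random(n) < 0.5).astype(int)
        if min(W.sum(), n - W.sum()) < 10:
            W[:20] = np.tile([0, 1], 10)
        tau = np.where(X[:, 1] <= 5, -1.0, 1.0)
        D = tau + rng.normal(0, 0.5, n)
        rows = np.arange(n)
        root = grow_tree(X, W, D, rows, min_leaf=5, max_depth=1)
        oracle = brute_force_root_split(X, D, W, rows, min_leaf=5)
        assert not root.is_leaf
        assert (root.feature_idx, root.threshold) == (oracle[1], oracle[2])

    def test_noiseless_step_recovers_exact_boundary(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 11, size=(40, 2)).astype(float)
        W = np.tile([0, 1], 20)
        D = np.where(X[:, 0] <= 5, -2.0, 1.0)
        root = grow_tree(X, W, D, np.arange(40), min_leaf=2, max_depth=1)
        oracle = brute_force_root_split(X, D, W, np.arange(40), min_leaf=2)
        assert (root.feature_idx, root.threshold) == (oracle[1], oracle[2])
        assert root.feature_idx == 0

    def test_arm_means_statistic_matches_its_own_oracle(self):
        rng = np.random.default_rng(7)
        n = 150
        X = rng.integers(1, 7, size=(n, 3)).astype(float)
        W = np.tile([0, 1], 75)
        y = rng.normal(size=n) + np.where(X[:, 2] <= 3, 0.0, 2.0) * W
        root = grow_tree(
            X, W, y, np.arange(n), min_leaf=5, max_depth=1, split_statistic="aipw_arm_means"
        )
        oracle = brute_force_root_split(X, y, W, np.arange(n), 5, "aipw_arm_means")
        assert (root.feature_idx, root.threshold) == (oracle[1], oracle[2])


class TestEstimateLeaves:
    def test_single_leaf_equals_restricted_ate(self, step_data):
        ds, sc = step_data
        s_idx, e_idx = split_honest_halves(ds.n, ds.W, seed=2)
        model = estimate_leaves(TreeNode(), ds.X, ds.W, sc.effect_score, e_idx)
        assert model.root.tau_hat == pytest.approx(sc.effect_score[e_idx].mean())

    def test_leaf_estimates_ignore_structure_half_outcomes(self, step_data):
        """Honesty: permuting structure-half scores leaves leaves unchanged."""
        ds, sc = step_data
        s_idx, e_idx = split_honest_halves(ds.n, ds.W, seed=2)
        structure = grow_tree(
            ds.X, ds.W, sc.effect_score, s_idx, min_leaf=50, max_depth=3
        )
        base = estimate_leaves(structure, ds.X, ds.W, sc.effect_score, e_idx)
        rng = np.random.default_rng(0)
        D2 = sc.effect_score.copy()
        D2[s_idx] = rng.permutation(D2[s_idx])
        perm = estimate_leaves(structure, ds.X, ds.W, D2, e_idx)
        for a, b in zip(base.root.leaves(), perm.root.leaves()):
            assert a.tau_hat == b.tau_hat and a.se == b.se

    def test_underpopulated_leaf_merges_with_sibling(self):
        X = pd.DataFrame({"x": [1, 1, 2, 2, 3, 3, 4, 4]})
        W = np.array([1, 0, 1, 0, 1, 1, 1, 1])  # no controls at x > 2
        D = np.arange(8.0)
        structure = TreeNode(
            feature="x",
            feature_idx=0,
            threshold=2.5,
            left=TreeNode(),
            right=TreeNode(),
        )
        model = estimate_leaves(structure, X, W, D, np.arange(8))
        assert model.root.is_leaf  # right child lacked a control: merged
        assert model.root.n_est == 8

    def test_every_leaf_has_both_arms(self, step_data):
        ds, sc = step_data
        model = dc.fit_causal_tree(
            ds.X, ds.W, sc.y_aipw, sc.effect_score, seed=4, min_leaf=50, max_depth=3
        )
        for leaf in model.root.leaves():
            assert leaf.n_treat_est >= 1 and leaf.n_control_est >= 1


class TestPredict:
    def test_boundary_value_routes_left(self):
        left = TreeNode(tau_hat=-1.0, leaf_id=0)
        right = TreeNode(tau_hat=1.0, leaf_id=1)
        root = TreeNode(feature="x", feature_idx=0, threshold=2.0, left=left, right=right)
        model = dc.CausalTreeModel(
            root=root,
            feature_names=["x"],
            structure_idx=np.array([]),
            estimation_idx=np.array([0]),
            min_leaf=1,
            max_depth=1,
            seed=0,
        )
        assert predict_cate(model, {"x": 2.0}) == -1.0
        assert predict_cate(model, {"x": 2.0001}) == 1.0

    def test_missing_feature_rejected(self, step_data):
        ds, sc = step_data
        model = dc.fit_causal_tree(
            ds.X, ds.W, sc.y_aipw, sc.effect_score, seed=4, min_leaf=100, max_depth=2
        )
        with pytest.raises(KeyError):
            predict_cate(model, {"ses_decile": 5})

    def test_predict_agrees_with_membership_lookup(self, step_data):
        ds, sc = step_data
        model = dc.fit_causal_tree(
            ds.X, ds.W, sc.y_aipw, sc.effect_score, seed=4, min_leaf=50, max_depth=3
        )
        sample = ds.X.sample(1000, random_state=0)
        batch = predict_cate_batch(model, sample)
        single = np.array([predict_cate(model, row) for _, row in sample.iterrows()])
        assert np.array_equal(batch, single)

    def test_membership_partitions_and_is_order_invariant(self, step_data):
        ds, sc = step_data
        model = dc.fit_causal_tree(
            ds.X, ds.W, sc.y_aipw, sc.effect_score, seed=4, min_leaf=50, max_depth=3
        )
        member = leaf_membership(model, ds.X)
        ids = sorted(leaf.leaf_id for leaf in model.root.leaves())
        assert sorted(np.unique(member)) == ids
        est_member = member[model.estimation_idx]
        counts = {leaf.leaf_id: leaf.n_est for leaf in model.root.leaves()}
        for lid, n in counts.items():
            assert (est_member == lid).sum() == n
        assert sum(counts.values()) == len(model.estimation_idx)
        perm = np.random.default_rng(1).permutation(ds.n)
        assert np.array_equal(leaf_membership(model, ds.X.iloc[perm]), member[perm])


def test_step_scenario_recovery_small_batch():
    """Root split lands on the SES decile across a handful of seeds."""
    hits = 0
    for s in range(10):
        ds = dc.generate_dataset(dc.nhs_step_config(n=4000, seed=700 + s))
        sc = dc.compute_scores(ds, dc.fit_crossfit_nuisances(ds, learner_config="truth"))
        model = dc.fit_causal_tree(
            ds.X, ds.W, sc.y_aipw, sc.effect_score, seed=s, min_leaf=50, max_depth=2
        )
        if not model.root.is_leaf and model.root.feature == "ses_decile":
            hits += 1
    assert hits >= 9
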