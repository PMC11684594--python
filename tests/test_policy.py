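"""Policy values, learned policies, exhaustive tree search, evaluation."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

import drcate as dc
from drcate.policy import (
    fit_policy_tree,
    fraction_treated,
    nonparametric_policy,
    policy_contrast,
    policy_value,
    random_policy,
    treat_all,
    treat_none,
)


class TestPolicyValue:
    def test_toy_values(self, toy_scores):
        _, sc = toy_scores
        assert policy_value(treat_all(), sc).estimate == pytest.approx(4.0)
        assert policy_value(treat_none(), sc).estimate == pytest.approx(1.5)
        assert policy_value(random_policy(0.5), sc).estimate == pytest.approx(2.75)

    def test_contrast_identities(self, toy_scores, step_data):
        _, sc_toy = toy_scores
        c = policy_contrast(treat_all(), random_policy(0.5), sc_toy)
        assert c.estimate == pytest.approx(1.25)
        same = policy_contrast(treat_all(), treat_all(), sc_toy)
        assert same.estimate == 0.0 and same.se == 0.0
        _, sc = step_data
        ate = dc.ate_aipw(sc).estimate
        assert policy_contrast(treat_all(), treat_none(), sc).estimate == ate

    def test_out_of_range_assignment_rejected(self, toy_scores):
        _, sc = toy_scores
        bad = random_policy(0.5)
        bad.random_q = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            policy_value(bad, sc)


class TestNonparametric:
    def test_all_negative_cates_treat_everyone_under_minimisation(self):
        pol = nonparametric_policy(np.array([-1.0, -0.2]), "minimise")
        assert np.all(pol.assign(oob_cate=np.array([-1.0, -0.2])) == 1.0)

    def test_zero_boundary_semantics(self):
        tau = np.array([0.0])
        assert nonparametric_policy(tau, "maximise").assign(oob_cate=tau)[0] == 1.0
        assert nonparametric_policy(tau, "minimise").assign(oob_cate=tau)[0] == 0.0

    def test_in_sample_cates_refused(self):
        with pytest.raises(ValueError, match="in-sample"):
            nonparametric_policy(np.zeros(5), "minimise", cate_is_out_of_sample=False)

    def test_step_scenario_treated_share_matches_cell_enumeration(self, step_data):
        """Fraction treated under minimisation ~ P(tau < 0) = P(ses >= 7) = 0.4."""
        ds, sc = step_data
        forest = dc.fit_forest(ds, sc, dc.ForestConfig(B=150, min_leaf=20, max_depth=4, seed=2))
        oob = dc.predict_oob(forest, ds)
        pol = nonparametric_policy(oob, "minimise")
        assert abs(fraction_treated(pol, oob_cate=oob) - 0.4) < 0.05


def brute_force_best_depth1(Xmat, g0, g1, grids):
    """Independent enumeration of every depth-1 tree (and constants)."""
    best = max(g0.sum(), g1.sum())
    for f in range(Xmat.shape[1]):
        for thr in grids[f]:
            mask = Xmat[:, f] <= thr
            if not mask.any() or mask.all():
                continue
            val = max(g0[mask].sum(), g1[mask].sum()) + max(
                g0[~mask].sum(), g1[~mask].sum()
            )
            best = max(best, val)
    return best


class TestPolicyTree:
    def test_depth1_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for rep in range(5):
            n = 50
            Xmat = rng.integers(1, 6, size=(n, 3)).astype(float)
            g0 = rng.normal(size=n)
            g1 = rng.normal(size=n)
            sc = dc.DRScores(
                gamma0=g0, gamma1=g1, effect_score=g1 - g0, y_aipw=np.where(rng.random(n) < 0.5, g1, g0)
            )
            pol = fit_policy_tree(Xmat, sc, depth=1, direction="maximise", threshold_grid=20)
            from drcate.policy import _threshold_grid

            grids = _threshold_grid(Xmat, 20)
            oracle = brute_force_best_depth1(Xmat, g0, g1, grids)
            fitted = float(
                np.sum(np.where(pol.assign(Xmat) == 1.0, g1, g0))
            )
            assert fitted == pytest.approx(oracle)

    def test_true_sign_policy_is_optimal_over_all_assignments(self):
        """Noiseless oracle scores: the sign rule beats all 2^n policies."""
        rng = np.random.default_rng(1)
        n = 10
        tau = rng.normal(size=n)
        g0 = rng.normal(size=n)
        g1 = g0 + tau
        sign_value = np.where(tau < 0, g1, g0).sum()  # minimisation direction
        for bits in product([0, 1], repeat=n):
            pi = np.array(bits)
            value = np.where(pi == 1, g1, g0).sum()
            assert sign_value <= value + 1e-12

    def test_all_benefit_collapses_to_constant_action(self):
        rng = np.random.default_rng(2)
        n = 80
        Xmat = rng.integers(1, 5, size=(n, 2)).astype(float)
        g0 = rng.normal(size=n)
        g1 = g0 + 1.0  # everyone benefits under maximisation
        sc = dc.DRScores(gamma0=g0, gamma1=g1, effect_score=g1 - g0, y_aipw=g1)
        pol = fit_policy_tree(Xmat, sc, depth=2, direction="maximise")
        assert pol.tree.is_leaf and pol.tree.action == 1

    def test_training_value_dominates_constants_and_grows_with_depth(self, step_data):
        ds, sc = step_data
        rows = np.arange(1000)
        values = []
        for depth in (1, 2, 3):
            pol = fit_policy_tree(
                ds.X, sc, depth=depth, direction="minimise", threshold_grid=8, rows=rows
            )
            values.append(pol.train_value)
        assert values[0] >= values[1] >= values[2]  # minimisation: lower is better
        const_best = min(
            sc.gamma0[rows].mean(), sc.gamma1[rows].mean()
        )
        assert values[0] <= const_best + 1e-9

    def test_depth_guard(self, step_data):
        ds, sc = step_data
        with pytest.raises(ValueError, match="depth"):
            fit_policy_tree(ds.X, sc, depth=4)

    def test_minimum_training_rows_enforced(self, step_data):
        ds, sc = step_data
        with pytest.raises(ValueError, match="training rows"):
            fit_policy_tree(ds.X, sc, depth=3, rows=np.arange(50))

    def test_tree_fraction_matches_independent_routing(self, step_data):
        ds, sc = step_data
        pol = fit_policy_tree(ds.X, sc, depth=2, direction="minimise", rows=np.arange(2000))
        pi = pol.assign(ds.X)
        # independent routing: walk the tree per row in pure python
        def route(row):
            node = pol.tree
            while not node.is_leaf:
                node = node.left if row[node.feature_idx] <= node.threshold else node.right
            return float(node.action)

        Xmat = ds.X.to_numpy(float)
        manual = np.array([route(Xmat[i]) for i in range(0, ds.n, 7)])
        assert np.array_equal(pi[::7], manual)
        assert fraction_treated(pol, ds.X) == pytest.approx(pi.mean())


class TestEvaluatePolicies:
    def test_baseline_rows_and_fractions(self, step_data):
        ds, sc = step_data
        tab = dc.evaluate_policies(
            sc, ds.X, ds.W, oob_cate=None, direction="minimise", depths=(1,), split_seed=0
        ).set_index("policy")
        assert tab.loc["treat_all", "fraction_treated"] == 1.0
        assert tab.loc["treat_none", "fraction_treated"] == 0.0
        assert tab.loc["random_0.5", "fraction_treated"] == 0.5
        # treat-none estimate equals mean gamma0 on the held-out half
        from drcate.tree import split_honest_halves

        _, test_idx = split_honest_halves(ds.n, ds.W, 0)
        assert tab.loc["treat_none", "estimate"] == pytest.approx(
            sc.gamma0[test_idx].mean()
        )
        assert tab.loc["observed", "estimate"] == pytest.approx(
            sc.y_aipw[test_idx].mean()
        )

    def test_learned_policy_beats_random_on_step_scenario(self):
        wins = 0
        for s in range(10):
            ds = dc.generate_dataset(dc.nhs_step_config(n=4000, seed=300 + s))
            sc = dc.compute_scores(
                ds, dc.fit_crossfit_nuisances(ds, learner_config="truth")
            )
            from drcate.tree import split_honest_halves

            train, test = split_honest_halves(ds.n, ds.W, s)
            pol = fit_policy_tree(ds.X, sc, depth=2, direction="minimise", rows=train)
            gain = policy_contrast(random_policy(0.5), pol, sc, ds.X, rows=test).estimate
            if gain >= 0.1:
                wins += 1
        assert wins >= 8
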