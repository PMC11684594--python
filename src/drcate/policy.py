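"""Intervention-targeting policies valued with doubly robust scores.

A policy pi(x) in [0, 1] assigns treatment probabilistically; its value

    E[Y(pi(X))] ~= mean_i [ pi(x_i) * gamma1_i + (1 - pi(x_i)) * gamma0_i ]

is estimated by averaging the per-unit AIPW scores, so any two policies
can be compared on the same sample with a paired standard error.  The
contrast of treat-all against treat-none is algebraically the AIPW ATE.

Two learned policy families are provided:

* the *non-parametric* rule thresholds an out-of-bag CATE estimate at
  zero (treat benefiters); it needs no fitting but cannot be written down
  in terms of covariates;
* *policy trees*: depth-limited axis-aligned trees with leaf actions in
  {0, 1}, found by exhaustive search over per-feature quantile threshold
  grids, maximising (or minimising) the empirical policy value.  The
  search space nests by depth and contains both constant policies.

Learned policies are always evaluated on held-out rows: the train/test
split is stratified by treatment and the evaluator refuses to score a
tree on its own training rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .scores import DRScores, EffectEstimate, Z95
from .tree import split_honest_halves, _as_matrix

_EPS = 1e-9
MAX_DEPTH = 3
MIN_ROWS_PER_LEAF_BUDGET = 10  # training rows must exceed 2^depth * this


@dataclass
class PolicyTreeNode:
    feature_idx: Optional[int] = None
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["PolicyTreeNode"] = None
    right: Optional["PolicyTreeNode"] = None
    action: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.action is not None

    def assign(self, Xmat: np.ndarray) -> np.ndarray:
        out = np.empty(len(Xmat), dtype=float)

        def walk(node: "PolicyTreeNode", rows: np.ndarray) -> None:
            if node.is_leaf:
                out[rows] = float(node.action)
                return
            mask = Xmat[rows, node.feature_idx] <= node.threshold
            walk(node.left, rows[mask])
            walk(node.right, rows[~mask])

        walk(self, np.arange(len(Xmat)))
        return out


@dataclass
class Policy:
    """Treatment-assignment rule; ``assign`` returns pi per row."""

    form: str  # constant | random | cate_threshold | tree
    constant_action: Optional[int] = None
    random_q: Optional[float] = None
    direction: Optional[str] = None
    tree: Optional[PolicyTreeNode] = None
    feature_names: Optional[List[str]] = None
    depth: Optional[int] = None
    train_value: Optional[float] = None

    def assign(self, X=None, oob_cate: Optional[np.ndarray] = None, n: Optional[int] = None) -> np.ndarray:
        if self.form == "constant":
            size = self._resolve_n(X, oob_cate, n)
            return np.full(size, float(self.constant_action))
        if self.form == "random":
            size = self._resolve_n(X, oob_cate, n)
            return np.full(size, float(self.random_q))
        if self.form == "cate_threshold":
            if oob_cate is None:
                raise ValueError("cate_threshold policy needs an OOB CATE vector")
            tau = np.asarray(oob_cate, dtype=float)
            if self.direction == "minimise":
                return (tau < 0.0).astype(float)  # treat strictly-negative effects
            return (tau >= 0.0).astype(float)  # treat non-negative effects
        if self.form == "tree":
            if X is None:
                raise ValueError("tree policy needs covariates")
            Xmat, _ = _as_matrix(X)
            if isinstance(X, pd.DataFrame) and self.feature_names:
                Xmat = X[self.feature_names].to_numpy(dtype=float)
            return self.tree.assign(Xmat)
        raise ValueError(f"unknown policy form {self.form!r}")

    @staticmethod
    def _resolve_n(X, oob_cate, n) -> int:
        if X is not None:
            return len(X)
        if oob_cate is not None:
            return len(oob_cate)
        if n is not None:
            return n
        raise ValueError("cannot infer the number of rows")


def treat_all() -> Policy:
    return Policy(form="constant", constant_action=1)


def treat_none() -> Policy:
    return Policy(form="constant", constant_action=0)


def random_policy(q: float = 0.5) -> Policy:
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    return Policy(form="random", random_q=q)


def nonparametric_policy(
    oob_cate: np.ndarray,
    direction: str = "maximise",
    *,
    cate_is_out_of_sample: bool = True,
    allow_in_sample: bool = False,
) -> Policy:
    """Threshold-at-zero rule on an out-of-sample CATE estimate.

    With ``direction='maximise'`` units with tau_hat >= 0 are treated;
    with ``'minimise'`` units with tau_hat < 0 are treated (the boundary
    belongs to the treated set only under maximisation).  In-sample CATE
    estimates are refused unless explicitly overridden, because valuing a
    rule with the same rows that produced its CATEs is biased.
    """
    if direction not in ("maximise", "minimise"):
        raise ValueError("direction must be 'maximise' or 'minimise'")
    if not cate_is_out_of_sample and not allow_in_sample:
        raise ValueError(
            "refusing in-sample CATEs for policy construction; "
            "pass allow_in_sample=True to override"
        )
    np.asarray(oob_cate, dtype=float)  # shape/type check only
    return Policy(form="cate_threshold", direction=direction)


@dataclass(frozen=True)
class PolicyValue:
    estimate: float
    se: float
    fraction_treated: float

    @property
    def ci95(self) -> Tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)


def _pi_scores(pi: np.ndarray, scores: DRScores, rows: Optional[np.ndarray]) -> np.ndarray:
    g0, g1 = scores.gamma0, scores.gamma1
    if rows is not None:
        g0, g1 = g0[rows], g1[rows]
    if np.any(pi < -_EPS) or np.any(pi > 1 + _EPS):
        raise ValueError("policy assignments must lie in [0, 1]")
    return pi * g1 + (1.0 - pi) * g0


def policy_value(
    policy: Policy,
    scores: DRScores,
    X=None,
    oob_cate: Optional[np.ndarray] = None,
    rows: Optional[np.ndarray] = None,
) -> PolicyValue:
    """AIPW estimate of E[Y(pi(X))] with its standard error."""
    if rows is not None:
        Xr = X.iloc[rows] if isinstance(X, pd.DataFrame) else (X[rows] if X is not None else None)
        taur = oob_cate[rows] if oob_cate is not None else None
        pi = policy.assign(Xr, taur, n=len(rows))
    else:
        pi = policy.assign(X, oob_cate, n=scores.n)
    vals = _pi_scores(pi, scores, rows)
    est = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return PolicyValue(estimate=est, se=se, fraction_treated=float(np.mean(pi)))


def policy_contrast(
    pi_policy: Policy,
    pi_prime: Policy,
    scores: DRScores,
    X=None,
    oob_cate: Optional[np.ndarray] = None,
    rows: Optional[np.ndarray] = None,
) -> EffectEstimate:
    """Paired difference in value between two policies on the same rows."""
    n = len(rows) if rows is not None else scores.n
    if rows is not None:
        Xr = X.iloc[rows] if isinstance(X, pd.DataFrame) else (X[rows] if X is not None else None)
        taur = oob_cate[rows] if oob_cate is not None else None
    else:
        Xr, taur = X, oob_cate
    a = _pi_scores(pi_policy.assign(Xr, taur, n=n), scores, rows)
    b = _pi_scores(pi_prime.assign(Xr, taur, n=n), scores, rows)
    diff = a - b
    est = float(diff.mean())
    sd = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    se = sd / np.sqrt(len(diff))
    return EffectEstimate(est, se, (est - Z95 * se, est + Z95 * se), "policy_contrast")


def fraction_treated(policy: Policy, X=None, oob_cate=None, n=None) -> float:
    return float(np.mean(policy.assign(X, oob_cate, n=n)))


# ---------------------------------------------------------------------------
# Exhaustive policy-tree search
# ---------------------------------------------------------------------------


def _threshold_grid(Xmat: np.ndarray, cap: int) -> List[np.ndarray]:
    """Per-feature candidate thresholds: midpoints of consecutive distinct
    training values, thinned to at most ``cap`` quantiles when longer."""
    grids = []
    for f in range(Xmat.shape[1]):
        vals = np.unique(Xmat[:, f])
        if len(vals) < 2:
            grids.append(np.empty(0))
            continue
        mids = (vals[:-1] + vals[1:]) / 2.0
        if len(mids) > cap:
            qs = np.quantile(mids, np.linspace(0, 1, cap))
            mids = np.unique(qs)
        grids.append(mids)
    return grids


def _leaf_solution(s0: float, s1: float) -> Tuple[float, int]:
    """Best single action for summed (signed) scores; ties prefer action 0."""
    if s1 > s0 + _EPS:
        return s1, 1
    return s0, 0


def _solve_depth1(
    Xmat: np.ndarray,
    g0: np.ndarray,
    g1: np.ndarray,
    rows: np.ndarray,
    grids: List[np.ndarray],
) -> Tuple[float, PolicyTreeNode]:
    """Exact best depth-<=1 tree on the given rows (vectorised)."""
    s0, s1 = g0[rows].sum(), g1[rows].sum()
    best_val, action = _leaf_solution(s0, s1)
    best_node = PolicyTreeNode(action=action)
    for f, grid in enumerate(grids):
        if len(grid) == 0:
            continue
        v = Xmat[rows, f]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        c0 = np.concatenate([[0.0], np.cumsum(g0[rows][order])])
        c1 = np.concatenate([[0.0], np.cumsum(g1[rows][order])])
        pos = np.searchsorted(vs, grid, side="right")
        left = np.maximum(c0[pos], c1[pos])
        right = np.maximum(c0[-1] - c0[pos], c1[-1] - c1[pos])
        vals = left + right
        j = int(np.argmax(vals))
        if vals[j] > best_val + _EPS:
            thr = float(grid[j])
            p = pos[j]
            la = 1 if c1[p] > c0[p] + _EPS else 0
            ra = 1 if (c1[-1] - c1[p]) > (c0[-1] - c0[p]) + _EPS else 0
            best_val = float(vals[j])
            best_node = PolicyTreeNode(
                feature_idx=f,
                threshold=thr,
                left=PolicyTreeNode(action=la),
                right=PolicyTreeNode(action=ra),
            )
    return best_val, best_node


def _solve(
    Xmat: np.ndarray,
    g0: np.ndarray,
    g1: np.ndarray,
    rows: np.ndarray,
    depth: int,
    grids: List[np.ndarray],
) -> Tuple[float, PolicyTreeNode]:
    if depth <= 1:
        return _solve_depth1(Xmat, g0, g1, rows, grids)
    s0, s1 = g0[rows].sum(), g1[rows].sum()
    best_val, action = _leaf_solution(s0, s1)
    best_node = PolicyTreeNode(action=action)
    for f, grid in enumerate(grids):
        v = Xmat[rows, f]
        for thr in grid:
            mask = v <= thr
            if not mask.any() or mask.all():
                continue
            lv, ln = _solve(Xmat, g0, g1, rows[mask], depth - 1, grids)
            rv, rn = _solve(Xmat, g0, g1, rows[~mask], depth - 1, grids)
            if lv + rv > best_val + _EPS:
                best_val = lv + rv
                best_node = PolicyTreeNode(
                    feature_idx=f, threshold=float(thr), left=ln, right=rn
                )
    return best_val, best_node


def fit_policy_tree(
    X,
    scores: DRScores,
    depth: int = 2,
    direction: str = "maximise",
    threshold_grid: int = 20,
    seed: int = 0,
    rows: Optional[np.ndarray] = None,
) -> Policy:
    """Exhaustive search for the optimal depth-limited policy tree.

    Maximises (or minimises) the summed per-unit policy scores over all
    axis-aligned trees of the given depth with thresholds on per-feature
    quantile grids.  Deterministic tie-breaks: lower feature index, then
    lower threshold, then action 0 before 1; a split that does not
    strictly improve on a single action collapses to the constant policy.
    """
    if depth > MAX_DEPTH:
        raise ValueError(f"depth > {MAX_DEPTH} is not supported (exhaustive search)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if direction not in ("maximise", "minimise"):
        raise ValueError("direction must be 'maximise' or 'minimise'")
    Xmat, names = _as_matrix(X)
    rows = np.arange(len(Xmat)) if rows is None else np.asarray(rows)
    if len(rows) < (2**depth) * MIN_ROWS_PER_LEAF_BUDGET:
        raise ValueError(
            f"need at least {(2 ** depth) * MIN_ROWS_PER_LEAF_BUDGET} training rows "
            f"for depth {depth}"
        )
    sign = -1.0 if direction == "minimise" else 1.0
    g0 = sign * scores.gamma0
    g1 = sign * scores.gamma1
    grids = _threshold_grid(Xmat[rows], threshold_grid)
    val, node = _solve(Xmat, g0, g1, rows, depth, grids)

    def label(n: PolicyTreeNode) -> None:
        if n.is_leaf:
            return
        n.feature = names[n.feature_idx]
        label(n.left)
        label(n.right)

    label(node)
    return Policy(
        form="tree",
        tree=node,
        feature_names=names,
        direction=direction,
        depth=depth,
        train_value=float(sign * val / len(rows)),
    )


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------


def evaluate_policies(
    scores: DRScores,
    X,
    W: np.ndarray,
    oob_cate: Optional[np.ndarray] = None,
    direction: str = "maximise",
    depths: Sequence[int] = (1, 2, 3),
    threshold_grid: int = 20,
    split_seed: int = 0,
    extra_policies: Optional[Dict[str, Policy]] = None,
) -> pd.DataFrame:
    """Fit learned policies on a train half and value everything on test.

    The table includes the treat-all / treat-none / random(0.5) /
    observed-assignment baselines, the non-parametric CATE-threshold rule
    (when an OOB CATE is supplied) and policy trees of the requested
    depths, each with its estimate, standard error and treated fraction
    on the held-out half.
    """
    W = np.asarray(W)
    train_idx, test_idx = split_honest_halves(len(W), W, split_seed)
    rows = []

    def add(name: str, pol: Optional[Policy], pv: PolicyValue) -> None:
        rows.append(
            {
                "policy": name,
                "estimate": pv.estimate,
                "se": pv.se,
                "fraction_treated": pv.fraction_treated,
            }
        )

    for name, pol in (
        ("treat_all", treat_all()),
        ("treat_none", treat_none()),
        ("random_0.5", random_policy(0.5)),
    ):
        add(name, pol, policy_value(pol, scores, X, oob_cate, rows=test_idx))

    # observed assignment: pi = W, whose score is the observed-arm branch
    obs_vals = scores.y_aipw[test_idx]
    add(
        "observed",
        None,
        PolicyValue(
            estimate=float(obs_vals.mean()),
            se=float(obs_vals.std(ddof=1) / np.sqrt(len(obs_vals))),
            fraction_treated=float(W[test_idx].mean()),
        ),
    )

    if oob_cate is not None:
        np_pol = nonparametric_policy(oob_cate, direction)
        add("nonparametric", np_pol, policy_value(np_pol, scores, X, oob_cate, rows=test_idx))

    for depth in depths:
        pol = fit_policy_tree(
            X,
            scores,
            depth=depth,
            direction=direction,
            threshold_grid=threshold_grid,
            seed=split_seed,
            rows=train_idx,
        )
        add(f"tree_depth_{depth}", pol, policy_value(pol, scores, X, oob_cate, rows=test_idx))

    for name, pol in (extra_policies or {}).items():
        add(name, pol, policy_value(pol, scores, X, oob_cate, rows=test_idx))

    return pd.DataFrame(rows)
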