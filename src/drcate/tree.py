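"""Honest causal trees on doubly robust transformed outcomes.

An honest tree separates model selection from estimation: the sample is
split 50/50 (stratified by treatment); the *structure* half chooses the
recursive partition, the *estimation* half supplies the leaf effects.
Because a leaf's estimate never sees the rows that chose its boundaries,
the usual adaptive-selection bias of recursive partitioning is removed.

Structure search maximises sum_c n_c * tau_c^2 over children c, i.e. the
between-child heterogeneity of treatment effects, where tau_c is a child
effect estimate.  Two split statistics are available:

* ``"effect_score"`` (default): tau_c = mean(D | c), the child mean of the
  per-unit doubly robust effect score.  Since E[D | X] = tau(X) whenever
  either nuisance model is correct, child means are unbiased child CATEs
  regardless of how treatment assignment tilts X within a child.
* ``"aipw_arm_means"``: tau_c = mean(Y^AIPW | W=1, c) - mean(Y^AIPW | W=0, c),
  the arm contrast of the AIPW-transformed outcome, treating the
  transformed data as if randomised.  The transform corrects each arm's
  conditional *level* (E[Y^AIPW | W=w, X] = mu_w(X)) but not the
  compositional difference in X between arms inside a child, so under
  confounding this statistic partly tracks propensity covariates rather
  than effect modifiers; it is provided for comparison and matches the
  default exactly on randomised data in expectation.

Splits are admissible only when both children keep at least ``min_leaf``
structure units of each arm.  Leaf effects on the estimation half default
to means of the doubly robust effect score D (with sd/sqrt(n) standard
errors); arm-wise means of Y^AIPW are available as an alternative.

All covariates are ordered integer codes, so every split is a threshold
split with midpoint thresholds; ties route left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

_EPS = 1e-12


@dataclass
class TreeNode:
    # internal-node fields
    feature: Optional[str] = None
    feature_idx: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    # leaf fields (filled by honest estimation)
    tau_hat: Optional[float] = None
    se: Optional[float] = None
    n_est: int = 0
    n_treat_est: int = 0
    n_control_est: int = 0
    leaf_id: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


@dataclass
class CausalTreeModel:
    root: TreeNode
    feature_names: List[str]
    structure_idx: np.ndarray
    estimation_idx: np.ndarray
    min_leaf: int
    max_depth: int
    seed: int
    leaf_estimator: str = "effect_score"

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())


def split_honest_halves(
    n: int, W: np.ndarray, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified-by-arm 50/50 split into structure and estimation halves."""
    W = np.asarray(W)
    rng = np.random.default_rng(seed)
    structure: List[np.ndarray] = []
    estimation: List[np.ndarray] = []
    for arm in (0, 1):
        idx = np.flatnonzero(W == arm)
        if len(idx) < 2:
            raise ValueError(f"arm {arm} has fewer than 2 units; cannot halve")
        rng.shuffle(idx)
        half = len(idx) // 2
        structure.append(idx[:half])
        estimation.append(idx[half:])
    s = np.sort(np.concatenate(structure))
    e = np.sort(np.concatenate(estimation))
    return s, e


def _as_matrix(X) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


VALID_SPLIT_STATISTICS = ("effect_score", "aipw_arm_means")


def _node_criterion(y: np.ndarray, w: np.ndarray, statistic: str) -> float:
    """n * tau^2 for one node (0 when an arm is absent)."""
    if statistic == "effect_score":
        if len(y) == 0:
            return 0.0
        tau = y.mean()
        return len(y) * tau * tau
    n1 = w.sum()
    n0 = len(w) - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    tau = y[w == 1].mean() - y[w == 0].mean()
    return len(y) * tau * tau


def _best_split(
    Xmat: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    rows: np.ndarray,
    min_leaf: int,
    feature_subset: Sequence[int],
    statistic: str = "effect_score",
) -> Optional[Tuple[int, float, float]]:
    """Exhaustive (feature, threshold) search maximising child heterogeneity.

    Returns (feature_idx, threshold, criterion) for the best admissible
    split, or None.  Ties go to the lowest feature index, then the lowest
    threshold (guaranteed by scan order and strict improvement).
    """
    best: Optional[Tuple[int, float, float]] = None
    yr = y[rows]
    wr = w[rows].astype(float)
    m = len(rows)
    for f in feature_subset:
        v = Xmat[rows, f]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ys = yr[order]
        ws = wr[order]
        # candidate split positions: between consecutive distinct values
        distinct = np.flatnonzero(vs[:-1] < vs[1:])
        if len(distinct) == 0:
            continue
        n1 = np.cumsum(ws)
        n0 = np.cumsum(1.0 - ws)
        n1L, n0L = n1[distinct], n0[distinct]
        n1R, n0R = n1[-1] - n1L, n0[-1] - n0L
        ok = (
            (n1L >= min_leaf)
            & (n0L >= min_leaf)
            & (n1R >= min_leaf)
            & (n0R >= min_leaf)
        )
        if not ok.any():
            continue
        pos = distinct[ok]
        nL = pos + 1.0
        if statistic == "effect_score":
            c = np.cumsum(ys)
            tauL = c[pos] / nL
            tauR = (c[-1] - c[pos]) / (m - nL)
        else:
            c1 = np.cumsum(ys * ws)
            c0 = np.cumsum(ys * (1.0 - ws))
            n1L, n0L = n1[pos], n0[pos]
            n1R, n0R = n1[-1] - n1L, n0[-1] - n0L
            tauL = c1[pos] / n1L - c0[pos] / n0L
            tauR = (c1[-1] - c1[pos]) / n1R - (c0[-1] - c0[pos]) / n0R
        crit = nL * tauL**2 + (m - nL) * tauR**2
        j = int(np.argmax(crit))
        score = float(crit[j])
        if best is None or score > best[2] + _EPS:
            thr = float((vs[pos[j]] + vs[pos[j] + 1]) / 2.0)
            best = (f, thr, score)
    return best


def grow_tree(
    X: Union[pd.DataFrame, np.ndarray],
    W: np.ndarray,
    split_outcome: np.ndarray,
    structure_idx: np.ndarray,
    min_leaf: int = 50,
    max_depth: int = 4,
    seed: int = 0,
    mtry: Optional[int] = None,
    split_statistic: str = "effect_score",
) -> TreeNode:
    """Grow the split structure on the structure half (no leaf estimates).

    ``split_outcome`` is the working outcome the statistic consumes: the
    per-unit effect score D for ``split_statistic="effect_score"``, the
    transformed outcome Y^AIPW for ``"aipw_arm_means"``.  ``mtry``, when
    given, draws that many candidate features uniformly at each node (used
    by forests); otherwise every feature is considered.
    """
    if split_statistic not in VALID_SPLIT_STATISTICS:
        raise ValueError(f"unknown split statistic {split_statistic!r}")
    Xmat, names = _as_matrix(X)
    W = np.asarray(W)
    y = np.asarray(split_outcome, dtype=float)
    rng = np.random.default_rng(seed)
    d = Xmat.shape[1]

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode()
        if depth >= max_depth:
            return node
        if mtry is not None and mtry < d:
            subset = np.sort(rng.choice(d, size=mtry, replace=False))
        else:
            subset = np.arange(d)
        found = _best_split(Xmat, y, W, rows, min_leaf, subset, split_statistic)
        if found is None:
            return node
        f, thr, score = found
        parent = _node_criterion(y[rows], W[rows], split_statistic)
        if score <= parent + _EPS:
            return node
        mask = Xmat[rows, f] <= thr
        node.feature = names[f]
        node.feature_idx = f
        node.threshold = thr
        node.left = build(rows[mask], depth + 1)
        node.right = build(rows[~mask], depth + 1)
        return node

    return build(np.asarray(structure_idx), 0)


def estimate_leaves(
    structure: TreeNode,
    X: Union[pd.DataFrame, np.ndarray],
    W: np.ndarray,
    effect_score: np.ndarray,
    estimation_idx: np.ndarray,
    *,
    structure_idx: Optional[np.ndarray] = None,
    min_leaf: int = 50,
    max_depth: int = 4,
    seed: int = 0,
    leaf_estimator: str = "effect_score",
    y_aipw: Optional[np.ndarray] = None,
) -> CausalTreeModel:
    """Fill leaf effects from the estimation half (honest estimation).

    A leaf that receives no estimation unit from one arm is merged with
    its sibling, recursively, so every reported leaf has both arms.
    ``leaf_estimator`` selects between means of the doubly robust effect
    score (default) and arm-wise means of Y^AIPW.
    """
    Xmat, names = _as_matrix(X)
    W = np.asarray(W)
    D = np.asarray(effect_score, dtype=float)
    estimation_idx = np.asarray(estimation_idx)
    if len(estimation_idx) == 0:
        raise ValueError("estimation half is empty")
    if leaf_estimator not in ("effect_score", "arm_means_yaipw"):
        raise ValueError(f"unknown leaf estimator {leaf_estimator!r}")
    if leaf_estimator == "arm_means_yaipw":
        if y_aipw is None:
            raise ValueError("arm_means_yaipw estimator needs y_aipw")
        ya = np.asarray(y_aipw, dtype=float)

    def leaf_stats(node: TreeNode, rows: np.ndarray) -> Optional[TreeNode]:
        w = W[rows]
        n1 = int(w.sum())
        n0 = len(rows) - n1
        if n1 < 1 or n0 < 1:
            return None
        leaf = TreeNode()
        if leaf_estimator == "effect_score":
            vals = D[rows]
            leaf.tau_hat = float(vals.mean())
            leaf.se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        else:
            y1, y0 = ya[rows][w == 1], ya[rows][w == 0]
            leaf.tau_hat = float(y1.mean() - y0.mean())
            v1 = y1.var(ddof=1) / n1 if n1 > 1 else 0.0
            v0 = y0.var(ddof=1) / n0 if n0 > 1 else 0.0
            leaf.se = float(np.sqrt(v1 + v0))
        leaf.n_est = len(rows)
        leaf.n_treat_est = n1
        leaf.n_control_est = n0
        return leaf

    def walk(node: TreeNode, rows: np.ndarray) -> Optional[TreeNode]:
        if node.is_leaf:
            return leaf_stats(node, rows)
        mask = Xmat[rows, node.feature_idx] <= node.threshold
        left = walk(node.left, rows[mask])
        right = walk(node.right, rows[~mask])
        if left is None or right is None:
            return leaf_stats(node, rows)  # merge underpopulated children
        out = TreeNode(
            feature=node.feature,
            feature_idx=node.feature_idx,
            threshold=node.threshold,
            left=left,
            right=right,
        )
        return out

    root = walk(structure, estimation_idx)
    if root is None:
        raise ValueError("estimation half lacks one treatment arm entirely")
    for i, leaf in enumerate(root.leaves()):
        leaf.leaf_id = i
    return CausalTreeModel(
        root=root,
        feature_names=names,
        structure_idx=(
            np.asarray(structure_idx) if structure_idx is not None else np.array([], int)
        ),
        estimation_idx=estimation_idx,
        min_leaf=min_leaf,
        max_depth=max_depth,
        seed=seed,
        leaf_estimator=leaf_estimator,
    )


def fit_causal_tree(
    X: Union[pd.DataFrame, np.ndarray],
    W: np.ndarray,
    y_aipw: np.ndarray,
    effect_score: np.ndarray,
    seed: int = 0,
    min_leaf: int = 50,
    max_depth: int = 4,
    mtry: Optional[int] = None,
    leaf_estimator: str = "effect_score",
    split_statistic: str = "effect_score",
) -> CausalTreeModel:
    """Honest halves + structure growth + honest leaf estimation in one call."""
    W = np.asarray(W)
    n = len(W)
    s_idx, e_idx = split_honest_halves(n, W, seed)
    split_outcome = effect_score if split_statistic == "effect_score" else y_aipw
    structure = grow_tree(
        X,
        W,
        split_outcome,
        s_idx,
        min_leaf=min_leaf,
        max_depth=max_depth,
        seed=seed,
        mtry=mtry,
        split_statistic=split_statistic,
    )
    return estimate_leaves(
        structure,
        X,
        W,
        effect_score,
        e_idx,
        structure_idx=s_idx,
        min_leaf=min_leaf,
        max_depth=max_depth,
        seed=seed,
        leaf_estimator=leaf_estimator,
        y_aipw=y_aipw,
    )


def _route_matrix(root: TreeNode, Xmat: np.ndarray) -> np.ndarray:
    """Leaf id for every row (vectorised recursion; ties route left)."""
    out = np.empty(len(Xmat), dtype=np.int64)

    def walk(node: TreeNode, rows: np.ndarray) -> None:
        if node.is_leaf:
            out[rows] = node.leaf_id
            return
        mask = Xmat[rows, node.feature_idx] <= node.threshold
        walk(node.left, rows[mask])
        walk(node.right, rows[~mask])

    walk(root, np.arange(len(Xmat)))
    return out


def leaf_membership(model: CausalTreeModel, X) -> np.ndarray:
    Xmat, names = _as_matrix(X)
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        Xmat = X[model.feature_names].to_numpy(dtype=float)
    return _route_matrix(model.root, Xmat)


def predict_cate(model: CausalTreeModel, x) -> float:
    """Leaf effect for a single covariate row (Series, mapping or array)."""
    if isinstance(x, pd.Series) or isinstance(x, dict):
        try:
            vec = np.array([float(x[f]) for f in model.feature_names])
        except KeyError as err:
            raise KeyError(f"missing feature {err}") from err
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (len(model.feature_names),):
            raise ValueError("row length does not match the model's features")
    node = model.root
    while not node.is_leaf:
        node = node.left if vec[node.feature_idx] <= node.threshold else node.right
    return float(node.tau_hat)


def predict_cate_batch(model: CausalTreeModel, X) -> np.ndarray:
    member = leaf_membership(model, X)
    taus = np.array([leaf.tau_hat for leaf in model.root.leaves()])
    return taus[member]
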