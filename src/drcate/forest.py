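"""Causal forests: ensembles of honest trees on random subsamples.

Each tree is grown on an independent without-replacement subsample, with
its own honest structure/estimation halves and a fresh random draw of
``mtry`` candidate features at every split.  A unit's out-of-bag (OOB)
effect prediction averages only the trees whose subsample excluded it, so
the prediction is independent of the unit's own outcome — the property
the downstream calibration test and non-parametric policies rely on.

Variable importance is the plain split frequency: the share of all splits
across the forest that use each covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .data import Dataset
from .scores import DRScores
from . import tree as _tree
from .tree import CausalTreeModel, TreeNode


@dataclass(frozen=True)
class ForestConfig:
    B: int = 2000
    subsample_fraction: float = 0.5
    mtry: Optional[int] = None  # default ceil(sqrt(d)), resolved at fit time
    min_leaf: int = 50
    max_depth: int = 4
    seed: int = 0
    split_statistic: str = "effect_score"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must lie in (0, 1]")

    def resolved_mtry(self, d: int) -> int:
        return self.mtry if self.mtry is not None else int(math.ceil(math.sqrt(d)))


@dataclass
class CausalForestModel:
    trees: List[CausalTreeModel]
    subsample_of: List[np.ndarray]
    config: ForestConfig
    n: int
    feature_names: List[str]

    @property
    def B(self) -> int:
        return len(self.trees)


def fit_forest(
    dataset_or_X: Union[Dataset, pd.DataFrame, np.ndarray],
    scores: DRScores,
    config: ForestConfig = ForestConfig(),
) -> CausalForestModel:
    """Fit B honest causal trees on independent subsamples."""
    if isinstance(dataset_or_X, Dataset):
        X, W = dataset_or_X.X, dataset_or_X.W
    else:
        raise TypeError("fit_forest expects a Dataset")
    Xmat, names = _tree._as_matrix(X)
    n = len(W)
    s = int(round(config.subsample_fraction * n))
    if s < 4:
        raise ValueError("subsample too small for honest halves")
    mtry = config.resolved_mtry(Xmat.shape[1])
    ss = np.random.SeedSequence(config.seed)
    trees: List[CausalTreeModel] = []
    subsamples: List[np.ndarray] = []
    for b, child in enumerate(ss.spawn(config.B)):
        state = child.generate_state(2)
        rng = np.random.default_rng(int(state[0] >> 1))
        tree_seed = int(state[1] >> 1)
        sub = np.sort(rng.choice(n, size=s, replace=False))
        Wb = W[sub]
        if Wb.sum() < 2 * config.min_leaf or (len(sub) - Wb.sum()) < 2 * config.min_leaf:
            raise ValueError(
                f"subsample {b} cannot host min_leaf={config.min_leaf} per arm; "
                "lower min_leaf or raise subsample_fraction"
            )
        model = _tree.fit_causal_tree(
            Xmat[sub],
            Wb,
            scores.y_aipw[sub],
            scores.effect_score[sub],
            seed=tree_seed,
            min_leaf=config.min_leaf,
            max_depth=config.max_depth,
            mtry=mtry,
            split_statistic=config.split_statistic,
        )
        model.feature_names = list(names)
        trees.append(model)
        subsamples.append(sub)
    return CausalForestModel(
        trees=trees, subsample_of=subsamples, config=config, n=n, feature_names=list(names)
    )


def _tree_predictions(model: CausalForestModel, Xmat: np.ndarray) -> np.ndarray:
    """(B, n_rows) matrix of per-tree leaf effects."""
    preds = np.empty((model.B, len(Xmat)))
    for b, t in enumerate(model.trees):
        member = _tree._route_matrix(t.root, Xmat)
        taus = np.array([leaf.tau_hat for leaf in t.root.leaves()])
        preds[b] = taus[member]
    return preds


def predict(model: CausalForestModel, X_new) -> np.ndarray:
    """Plain forest prediction: average effect over all B trees."""
    Xmat, _ = _tree._as_matrix(X_new)
    if isinstance(X_new, pd.DataFrame):
        Xmat = X_new[model.feature_names].to_numpy(dtype=float)
    return _tree_predictions(model, Xmat).mean(axis=0)


def predict_oob(model: CausalForestModel, dataset: Dataset) -> np.ndarray:
    """Out-of-bag CATE: average over trees whose subsample excludes the unit."""
    if dataset.n != model.n:
        raise ValueError("dataset does not match the fitted forest")
    Xmat = dataset.X[model.feature_names].to_numpy(dtype=float)
    in_bag = np.zeros((model.B, model.n), dtype=bool)
    for b, sub in enumerate(model.subsample_of):
        in_bag[b, sub] = True
    preds = _tree_predictions(model, Xmat)
    oob_mask = ~in_bag
    counts = oob_mask.sum(axis=0)
    if (counts == 0).any():
        offenders = np.flatnonzero(counts == 0)[:5].tolist()
        raise ValueError(
            f"units {offenders} appear in every subsample; increase B or "
            "decrease subsample_fraction"
        )
    return (preds * oob_mask).sum(axis=0) / counts


def variable_importance(model: CausalForestModel) -> Dict[str, float]:
    """Split-frequency importance, normalised to sum to one.

    A forest of single-leaf trees has no splits; all weights are zero and
    the caller can detect that by the sum.
    """
    counts = {name: 0 for name in model.feature_names}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        counts[model.feature_names[node.feature_idx]] += 1
        walk(node.left)
        walk(node.right)

    for t in model.trees:
        walk(t.root)
    total = sum(counts.values())
    if total == 0:
        return {name: 0.0 for name in model.feature_names}
    return {name: c / total for name, c in counts.items()}
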