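"""Cross-fitted nuisance estimation: outcome models, propensity, overlap.

Doubly robust estimation needs two nuisance functions — the arm-wise
outcome regression mu(x, w) = E[Y | X=x, W=w] and the propensity
p(x) = P(W=1 | X=x).  Both are estimated with K-fold cross-fitting: each
unit's predictions come from models fitted on the other folds, so no
unit's own outcome leaks into its own nuisance values.  Folds are
stratified by treatment so every training split contains both arms.

Learners: random forests by default (the outcome model is fitted
separately per arm, keeping mu(x,0) and mu(x,1) symmetric), plain linear /
logistic models for cheap smoke runs, and an oracle mode that passes the
synthetic generator's truth straight through for recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from .data import Dataset

DEFAULT_CLIP: Tuple[float, float] = (0.01, 0.99)
CLIP_WARN_SHARE = 0.02


@dataclass(frozen=True)
class FoldAssignment:
    fold_of: np.ndarray  # unit index -> fold id in {0..K-1}
    K: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_of, minlength=self.K)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")

    def train_mask(self, k: int) -> np.ndarray:
        return self.fold_of != k


@dataclass
class NuisanceEstimates:
    """Per-unit cross-fitted predictions plus clipping bookkeeping."""

    mu0: np.ndarray
    mu1: np.ndarray
    phat: np.ndarray
    clip_bounds: Tuple[float, float]
    n_clipped: int
    folds: Optional[FoldAssignment]

    @property
    def n(self) -> int:
        return len(self.phat)


def assign_folds(n: int, K: int, W: np.ndarray, seed: int) -> FoldAssignment:
    """Random K-fold partition stratified by treatment arm.

    Within each arm fold sizes differ by at most one; the larger folds of
    the second arm are steered toward the folds the first arm left small,
    so total fold sizes also differ by at most one.
    """
    W = np.asarray(W)
    if K < 2:
        raise ValueError("K must be >= 2")
    for arm in (0, 1):
        if (W == arm).sum() < K:
            raise ValueError(f"arm {arm} has fewer than K={K} units")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=np.int64)
    totals = np.zeros(K, dtype=np.int64)
    for arm in (1, 0):
        idx = np.flatnonzero(W == arm)
        rng.shuffle(idx)
        q, r = divmod(len(idx), K)
        # folds currently smallest receive this arm's remainder units
        order = np.lexsort((rng.random(K), totals))
        sizes = np.full(K, q, dtype=np.int64)
        sizes[order[:r]] += 1
        start = 0
        for k in range(K):
            fold_of[idx[start : start + sizes[k]]] = k
            start += sizes[k]
        totals += sizes
    return FoldAssignment(fold_of=fold_of, K=K)


def clip_propensity(
    p: np.ndarray, lo: float, hi: float
) -> Tuple[np.ndarray, int]:
    """Element-wise clamp of propensities, counting modified entries."""
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("clip bounds must satisfy 0 < lo < hi < 1")
    p = np.asarray(p, dtype=float)
    clipped = np.clip(p, lo, hi)
    n_clipped = int((clipped != p).sum())
    return clipped, n_clipped


def _make_regressor(config: Mapping, seed: int):
    kind = config.get("kind", "rf")
    if kind == "rf":
        return RandomForestRegressor(
            n_estimators=int(config.get("n_estimators", 500)),
            min_samples_leaf=int(config.get("min_samples_leaf", 5)),
            max_depth=config.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "linear":
        return LinearRegression()
    raise ValueError(f"unknown learner kind {kind!r}")


def _make_classifier(config: Mapping, seed: int):
    kind = config.get("kind", "rf")
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(config.get("n_estimators", 500)),
            min_samples_leaf=int(config.get("min_samples_leaf", 5)),
            max_depth=config.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "linear":
        return LogisticRegression(max_iter=1000)
    raise ValueError(f"unknown learner kind {kind!r}")


def fit_crossfit_nuisances(
    dataset: Dataset,
    K: int = 5,
    learner_config: Optional[Mapping] = None,
    seed: int = 0,
    clip_bounds: Tuple[float, float] = DEFAULT_CLIP,
) -> NuisanceEstimates:
    """Cross-fitted mu(x,0), mu(x,1) and clipped propensity p(x).

    ``learner_config`` is either the string ``"truth"`` (oracle mode:
    synthetic ground truth passed through, no fitting) or a mapping with a
    ``kind`` key (``rf`` or ``linear``) plus learner hyperparameters.
    """
    n = dataset.n
    if dataset.n_treated == 0 or dataset.n_control == 0:
        raise ValueError("dataset must contain both treated and control units")

    if learner_config == "truth":
        t = dataset.truth
        if t is None:
            raise ValueError("oracle nuisances require synthetic ground truth")
        phat, n_clipped = clip_propensity(t.propensity, *clip_bounds)
        return NuisanceEstimates(
            mu0=t.mu0.copy(),
            mu1=t.mu0 + t.cate,
            phat=phat,
            clip_bounds=clip_bounds,
            n_clipped=n_clipped,
            folds=None,
        )

    config = dict(learner_config or {"kind": "rf"})
    folds = assign_folds(n, K, dataset.W, seed)
    Xmat = dataset.covariate_matrix()
    W, Y = dataset.W, dataset.Y
    mu0 = np.empty(n)
    mu1 = np.empty(n)
    phat_raw = np.empty(n)
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] >> 1) for s in ss.spawn(K)]
    for k in range(K):
        train = folds.train_mask(k)
        held = ~train
        for arm in (0, 1):
            if not (W[train] == arm).any():
                raise ValueError(f"training split for fold {k} lacks arm {arm}")
        prop = _make_classifier(config, fold_seeds[k])
        prop.fit(Xmat[train], W[train])
        proba = prop.predict_proba(Xmat[held])
        col = int(np.flatnonzero(prop.classes_ == 1)[0])
        phat_raw[held] = proba[:, col]
        for arm, out in ((0, mu0), (1, mu1)):
            sel = train & (W == arm)
            reg = _make_regressor(config, fold_seeds[k] + arm + 1)
            if np.ptp(Y[sel]) == 0.0:
                out[held] = Y[sel][0]  # degenerate constant outcome
                continue
            reg.fit(Xmat[sel], Y[sel])
            out[held] = reg.predict(Xmat[held])
    phat, n_clipped = clip_propensity(phat_raw, *clip_bounds)
    if n_clipped > CLIP_WARN_SHARE * n:
        warnings.warn(
            f"{n_clipped}/{n} propensities clipped to {clip_bounds}; "
            "estimates may be unreliable near the overlap boundary",
            stacklevel=2,
        )
    return NuisanceEstimates(
        mu0=mu0,
        mu1=mu1,
        phat=phat,
        clip_bounds=clip_bounds,
        n_clipped=n_clipped,
        folds=folds,
    )


def overlap_diagnostics(phat: np.ndarray, bins: int = 20) -> Dict:
    """Histogram plus summary of the estimated propensity distribution.

    ``overlap_ok`` is true when all propensities lie strictly inside
    (0, 1); ``share_extreme`` is the fraction outside [0.05, 0.95].
    """
    phat = np.asarray(phat, dtype=float)
    if phat.size == 0:
        raise ValueError("phat must be non-empty")
    counts, edges = np.histogram(phat, bins=bins, range=(0.0, 1.0))
    share_extreme = float(((phat < 0.05) | (phat > 0.95)).mean())
    return {
        "bin_counts": counts.tolist(),
        "bin_edges": edges.tolist(),
        "min": float(phat.min()),
        "max": float(phat.max()),
        "share_extreme": share_extreme,
        "overlap_ok": bool(phat.min() > 0.0 and phat.max() < 1.0),
    }
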