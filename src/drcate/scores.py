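"""Doubly robust per-unit scores, ATE estimators and balance diagnostics.

The AIPW construction assigns each unit two scores

    gamma1_i = mu(x_i, 1) + W_i / p(x_i) * (Y_i - mu(x_i, 1))
    gamma0_i = mu(x_i, 0) + (1 - W_i) / (1 - p(x_i)) * (Y_i - mu(x_i, 0))

whose difference D_i = gamma1_i - gamma0_i averages to the doubly robust
ATE estimate: unbiased when either the outcome model or the propensity
model is correct.  The transformed outcome Y^AIPW_i is the observed-arm
branch of the same construction (gamma1 for treated units, gamma0 for
controls); it is used as the working outcome when searching for tree
structure, while all inference uses the effect score D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .data import Dataset
from .nuisance import NuisanceEstimates

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass
class DRScores:
    gamma0: np.ndarray
    gamma1: np.ndarray
    effect_score: np.ndarray  # D = gamma1 - gamma0
    y_aipw: np.ndarray  # observed-arm branch of the score

    @property
    def n(self) -> int:
        return len(self.effect_score)


@dataclass(frozen=True)
class EffectEstimate:
    estimate: float
    se: float
    ci95: Tuple[float, float]
    method: str

    @classmethod
    def from_mean(cls, values: np.ndarray, method: str) -> "EffectEstimate":
        values = np.asarray(values, dtype=float)
        est = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(len(values)))
        return cls(est, se, (est - Z95 * se, est + Z95 * se), method)


def compute_scores(dataset: Dataset, nuis: NuisanceEstimates) -> DRScores:
    """Per-unit doubly robust scores from cross-fitted nuisances."""
    if nuis.n != dataset.n:
        raise ValueError("nuisance estimates not aligned with dataset")
    p = np.asarray(nuis.phat, dtype=float)
    if (p <= 0.0).any() or (p >= 1.0).any():
        raise ValueError("propensities must be clipped strictly inside (0, 1)")
    W = dataset.W
    Y = dataset.Y
    gamma1 = nuis.mu1 + W / p * (Y - nuis.mu1)
    gamma0 = nuis.mu0 + (1 - W) / (1 - p) * (Y - nuis.mu0)
    y_aipw = np.where(W == 1, gamma1, gamma0)
    return DRScores(
        gamma0=gamma0, gamma1=gamma1, effect_score=gamma1 - gamma0, y_aipw=y_aipw
    )


def ate_aipw(scores: DRScores) -> EffectEstimate:
    """Doubly robust ATE: mean effect score with influence-function SE."""
    if scores.n < 2:
        raise ValueError("need at least 2 units")
    return EffectEstimate.from_mean(scores.effect_score, "aipw")


def ate_diff_means(dataset: Dataset) -> EffectEstimate:
    """Naive difference-in-means estimator with a Welch standard error."""
    y1 = dataset.Y[dataset.W == 1]
    y0 = dataset.Y[dataset.W == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError("both arms must be non-empty")
    est = float(y1.mean() - y0.mean())
    se = float(np.sqrt(y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)))
    return EffectEstimate(est, se, (est - Z95 * se, est + Z95 * se), "diff_means")


def _smd(x: np.ndarray, w_arm: np.ndarray, weights: np.ndarray) -> float:
    """Weighted standardised mean difference between arms for one column."""
    t = w_arm == 1
    c = ~t
    wt, wc = weights[t], weights[c]
    mt = float(np.average(x[t], weights=wt))
    mc = float(np.average(x[c], weights=wc))
    vt = float(np.average((x[t] - mt) ** 2, weights=wt))
    vc = float(np.average((x[c] - mc) ** 2, weights=wc))
    denom = np.sqrt((vt + vc) / 2.0)
    if denom == 0.0:
        return 0.0
    return (mt - mc) / denom


def balance_table(dataset: Dataset, phat: np.ndarray) -> pd.DataFrame:
    """Standardised mean differences before and after IPW weighting.

    Weights are W/p + (1-W)/(1-p); a well-specified propensity drives the
    weighted SMD of every confounder toward zero.
    """
    phat = np.asarray(phat, dtype=float)
    W = dataset.W
    ones = np.ones(dataset.n)
    ipw = W / phat + (1 - W) / (1 - phat)
    rows = []
    for col in dataset.X.columns:
        x = dataset.X[col].to_numpy(dtype=float)
        rows.append(
            {
                "covariate": col,
                "smd_unweighted": _smd(x, W, ones),
                "smd_weighted": _smd(x, W, ipw),
                "mean_treated": float(x[W == 1].mean()),
                "mean_control": float(x[W == 0].mean()),
                "mean_treated_weighted": float(
                    np.average(x[W == 1], weights=ipw[W == 1])
                ),
                "mean_control_weighted": float(
                    np.average(x[W == 0], weights=ipw[W == 0])
                ),
            }
        )
    return pd.DataFrame(rows)
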