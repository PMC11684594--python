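"""Heterogeneity detection and subgroup inference with multiplicity control.

Three layers of inference sit on top of the per-unit doubly robust effect
scores D:

* a best-linear-predictor *calibration test* regressing D on the forest's
  mean OOB prediction and the centred OOB prediction (no intercept,
  heteroskedasticity-robust SEs); a one-sided test of the differential
  coefficient beta > 0 detects real heterogeneity captured by the forest;
* *group CATEs*: within-group means of D with sd/sqrt(n) standard errors,
  for pre-specified groups or tree leaves;
* *pairwise contrasts* between groups with Bonferroni or Romano-Wolf
  stepdown adjustment.  Romano-Wolf resamples units within groups,
  recentres each group at its observed mean (imposing the null) and
  adjusts by the stepdown max-statistic rule, which is less conservative
  than Bonferroni while still controlling the family-wise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .tree import CausalTreeModel, leaf_membership


@dataclass(frozen=True)
class CalibrationResult:
    alpha_hat: float  # mean-prediction coefficient (~1 when level is right)
    beta_hat: Optional[float]  # differential coefficient (~1 under real HTE)
    se_alpha: float
    se_beta: Optional[float]
    p_beta_one_sided: Optional[float]

    @property
    def heterogeneity_detected(self) -> Optional[bool]:
        if self.p_beta_one_sided is None:
            return None
        return self.p_beta_one_sided < 0.05


@dataclass(frozen=True)
class GroupCATE:
    group: object
    tau_hat: float
    se: float
    n: int


def calibration_test(
    effect_score: np.ndarray, oob_cate: np.ndarray, seed: int = 0
) -> CalibrationResult:
    """Best-linear-predictor calibration of forest CATEs against D.

    Regress D_i on (mean(tau_hat), tau_hat_i - mean(tau_hat)) without an
    intercept, using HC1 robust standard errors.  beta > 0 indicates the
    forest's ranking of units carries real effect heterogeneity; the
    one-sided p-value tests H0: beta <= 0.
    """
    D = np.asarray(effect_score, dtype=float)
    tau = np.asarray(oob_cate, dtype=float)
    if len(D) != len(tau):
        raise ValueError("effect_score and oob_cate must be aligned")
    mean_pred = np.full(len(tau), tau.mean())
    diff_pred = tau - tau.mean()
    if np.allclose(diff_pred, 0.0):
        # constant predictions: the differential coefficient is undefined
        fit = sm.OLS(D, mean_pred[:, None]).fit(cov_type="HC1")
        return CalibrationResult(
            alpha_hat=float(fit.params[0]),
            beta_hat=None,
            se_alpha=float(fit.bse[0]),
            se_beta=None,
            p_beta_one_sided=None,
        )
    Z = np.column_stack([mean_pred, diff_pred])
    fit = sm.OLS(D, Z).fit(cov_type="HC1")
    beta, se_beta = float(fit.params[1]), float(fit.bse[1])
    p_one_sided = float(stats.norm.sf(beta / se_beta))
    return CalibrationResult(
        alpha_hat=float(fit.params[0]),
        beta_hat=beta,
        se_alpha=float(fit.bse[0]),
        se_beta=se_beta,
        p_beta_one_sided=p_one_sided,
    )


def group_cate(effect_score: np.ndarray, groups: Sequence) -> List[GroupCATE]:
    """Within-group means of the effect score; groups with n < 2 dropped."""
    D = np.asarray(effect_score, dtype=float)
    g = np.asarray(groups)
    if len(D) != len(g):
        raise ValueError("effect_score and groups must be aligned")
    out: List[GroupCATE] = []
    for label in pd.unique(g):
        vals = D[g == label]
        if len(vals) < 2:
            warnings.warn(f"group {label!r} has n < 2; dropped", stacklevel=2)
            continue
        out.append(
            GroupCATE(
                group=label,
                tau_hat=float(vals.mean()),
                se=float(vals.std(ddof=1) / np.sqrt(len(vals))),
                n=len(vals),
            )
        )
    return out


def pairwise_tests(groups: List[GroupCATE]) -> pd.DataFrame:
    """All unordered pairwise contrasts with two-sided normal p-values."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for pairwise tests")
    rows = []
    for a, b in combinations(groups, 2):
        diff = a.tau_hat - b.tau_hat
        se = float(np.sqrt(a.se**2 + b.se**2))
        z = diff / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 1.0
        rows.append(
            {
                "group_a": a.group,
                "group_b": b.group,
                "difference": diff,
                "se": se,
                "z": z,
                "p_raw": p,
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_group_stats(
    effect_score: np.ndarray,
    groups: np.ndarray,
    labels: Sequence,
    n_boot: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """(n_boot, k) matrices of recentred bootstrap means and their SEs.

    Units are resampled with replacement within each group and each
    group's bootstrap means are recentred at the observed mean, imposing
    the global null for the stepdown procedure.
    """
    k = len(labels)
    means = np.empty((n_boot, k))
    ses = np.empty((n_boot, k))
    for j, label in enumerate(labels):
        vals = effect_score[groups == label]
        m = len(vals)
        idx = rng.integers(0, m, size=(n_boot, m))
        draws = vals[idx]
        means[:, j] = draws.mean(axis=1) - vals.mean()
        ses[:, j] = draws.std(axis=1, ddof=1) / np.sqrt(m)
    return means, ses


def adjust_pvalues(
    table: pd.DataFrame,
    method: str,
    effect_score: Optional[np.ndarray] = None,
    groups: Optional[Sequence] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multiplicity-adjusted p-values for a pairwise contrast table.

    ``bonferroni`` multiplies by the number of hypotheses; ``romano_wolf``
    runs the studentised bootstrap stepdown with within-group recentring
    and needs the raw effect scores and group labels.
    """
    table = table.copy()
    m = len(table)
    if method == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p_raw"] * m)
        table["method"] = "bonferroni"
        return table
    if method != "romano_wolf":
        raise ValueError(f"unknown adjustment method {method!r}")
    if effect_score is None or groups is None:
        raise ValueError("romano_wolf needs effect_score and groups")
    if n_boot < 500:
        raise ValueError("romano_wolf needs n_boot >= 500")
    if m == 1:
        # a single hypothesis needs no multiplicity adjustment
        table["p_adjusted"] = table["p_raw"]
        table["method"] = "romano_wolf"
        return table
    D = np.asarray(effect_score, dtype=float)
    g = np.asarray(groups)
    labels = list(pd.unique(g))
    label_pos = {label: j for j, label in enumerate(labels)}
    rng = np.random.default_rng(seed)
    b_means, b_ses = _bootstrap_group_stats(D, g, labels, n_boot, rng)

    pairs = list(zip(table["group_a"], table["group_b"]))
    t_obs = np.abs(table["z"].to_numpy(dtype=float))
    # studentised bootstrap statistics per hypothesis
    t_boot = np.empty((n_boot, m))
    for j, (a, b) in enumerate(pairs):
        ja, jb = label_pos[a], label_pos[b]
        se = np.sqrt(b_ses[:, ja] ** 2 + b_ses[:, jb] ** 2)
        se = np.where(se > 0, se, np.inf)
        t_boot[:, j] = np.abs(b_means[:, ja] - b_means[:, jb]) / se

    order = np.argsort(-t_obs, kind="stable")  # most significant first
    adjusted = np.empty(m)
    remaining = order.tolist()
    prev = 0.0
    for j in order:
        max_stat = t_boot[:, remaining].max(axis=1)
        p = float((max_stat >= t_obs[j]).mean())
        prev = max(prev, p)  # enforce stepdown monotonicity
        adjusted[j] = prev
        remaining.remove(j)
    table["p_adjusted"] = np.minimum(1.0, np.maximum(adjusted, table["p_raw"]))
    table["method"] = "romano_wolf"
    return table


def leaf_heterogeneity_report(
    tree_model: CausalTreeModel,
    X,
    effect_score: np.ndarray,
    reference_leaf: Optional[int] = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Contrast every tree leaf against a reference leaf.

    By default the reference is the leaf with the largest-magnitude
    effect.  Contrasts use the estimation-half effect scores, with raw
    and Romano-Wolf-adjusted p-values in the usual report layout
    (Difference, Standard Error, Original p-value, Adjusted p-value).
    """
    leaves = tree_model.root.leaves()
    if len(leaves) < 2:
        return pd.DataFrame(
            columns=["leaf", "reference", "difference", "se", "z", "p_raw", "p_adjusted"]
        ).assign(note="single-leaf tree: no contrasts")
    est_idx = tree_model.estimation_idx
    member = leaf_membership(tree_model, X)[est_idx]
    D = np.asarray(effect_score, dtype=float)[est_idx]
    if reference_leaf is None:
        reference_leaf = int(
            max(leaves, key=lambda l: abs(l.tau_hat)).leaf_id
        )
    cates = group_cate(D, member)
    by_id = {gc.group: gc for gc in cates}
    ref = by_id[reference_leaf]
    rows = []
    for gc in cates:
        if gc.group == reference_leaf:
            continue
        diff = gc.tau_hat - ref.tau_hat
        se = float(np.sqrt(gc.se**2 + ref.se**2))
        z = diff / se if se > 0 else 0.0
        rows.append(
            {
                "group_a": gc.group,
                "group_b": reference_leaf,
                "difference": diff,
                "se": se,
                "z": z,
                "p_raw": float(2.0 * stats.norm.sf(abs(z))) if se > 0 else 1.0,
            }
        )
    rows.sort(key=lambda r: r["group_a"])
    raw = pd.DataFrame(rows)
    adj = adjust_pvalues(
        raw, "romano_wolf", effect_score=D, groups=member, n_boot=n_boot, seed=seed
    )
    adj = adj.rename(columns={"group_a": "leaf", "group_b": "reference"})
    return adj
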