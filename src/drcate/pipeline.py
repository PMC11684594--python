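"""End-to-end analysis pipeline: CSV in, reproducible report out.

``run_analysis`` chains the stages — cross-fitted nuisances, overlap
check, doubly robust scores and both ATE estimators, causal forest with
OOB predictions, the heterogeneity calibration test, optional
pre-specified subgroup contrasts, an honest causal tree with leaf
contrasts, and the policy comparison — under a single root seed that
deterministically spawns one seed per stage, so the whole report is
byte-reproducible for a fixed config and input.

The pipeline refuses to continue (unless forced) when the estimated
propensities violate the positivity diagnostic, since every downstream
quantity divides by p or 1-p.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import Dataset
from .forest import CausalForestModel, ForestConfig, fit_forest, predict_oob, variable_importance
from .inference import (
    adjust_pvalues,
    calibration_test,
    group_cate,
    leaf_heterogeneity_report,
    pairwise_tests,
)
from .nuisance import fit_crossfit_nuisances, overlap_diagnostics
from .policy import evaluate_policies, fit_policy_tree
from .render import render_dot, render_tree_text
from .scores import ate_aipw, ate_diff_means, balance_table, compute_scores
from .tree import fit_causal_tree

VALID_COVARIATE_KINDS = ("ordinal", "binary", "count")


class OverlapError(RuntimeError):
    """Raised when the positivity diagnostic fails and --force is absent."""


@dataclass
class RunConfig:
    input: str
    covariates: Dict[str, str]  # name -> kind
    treatment: str = "W"
    outcome: str = "Y"
    seed: int = 0
    direction: str = "minimise"
    nuisance: Dict = field(
        default_factory=lambda: {
            "learner": "rf",
            "folds": 5,
            "clip": [0.01, 0.99],
            "n_estimators": 200,
        }
    )
    forest: Dict = field(
        default_factory=lambda: {
            "B": 200,
            "subsample_fraction": 0.5,
            "min_leaf": 20,
            "max_depth": 4,
        }
    )
    tree: Dict = field(default_factory=lambda: {"min_leaf": 50, "max_depth": 3})
    policy: Dict = field(default_factory=lambda: {"depths": [1, 2], "threshold_grid": 20})
    testing: Dict = field(default_factory=lambda: {"groups": [], "n_boot": 1000})
    overlap: Dict = field(default_factory=lambda: {"max_clip_share": 0.1})
    outdir: str = "results"

    def __post_init__(self) -> None:
        for name, kind in self.covariates.items():
            if kind not in VALID_COVARIATE_KINDS:
                raise ValueError(f"covariate {name!r} has unknown kind {kind!r}")
        if self.direction not in ("minimise", "maximise"):
            raise ValueError("direction must be 'minimise' or 'maximise'")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> Dict:
        return {
            "input": self.input,
            "covariates": dict(self.covariates),
            "treatment": self.treatment,
            "outcome": self.outcome,
            "seed": self.seed,
            "direction": self.direction,
            "nuisance": dict(self.nuisance),
            "forest": dict(self.forest),
            "tree": dict(self.tree),
            "policy": dict(self.policy),
            "testing": dict(self.testing),
            "overlap": dict(self.overlap),
            "outdir": self.outdir,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    report: Dict
    tables: Dict[str, pd.DataFrame]
    dot: Dict[str, str]


def load_dataset(path: str, config: RunConfig) -> Tuple[Dataset, Dict, int]:
    """Read a CSV into a Dataset, coercing factors to integer codes.

    Non-numeric factor columns are mapped to codes 1..L in sorted level
    order (level maps returned for rendering); rows with a missing value
    in any declared column are dropped and the count reported.
    """
    df = pd.read_csv(path)
    declared = list(config.covariates) + [config.treatment, config.outcome]
    missing_cols = [c for c in declared if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input lacks declared columns: {missing_cols}")
    df = df[declared]
    n_before = len(df)
    df = df.dropna(subset=declared)
    n_dropped = n_before - len(df)

    level_maps: Dict[str, Dict[int, str]] = {}
    X = pd.DataFrame(index=df.index)
    for name, kind in config.covariates.items():
        col = df[name]
        if not pd.api.types.is_numeric_dtype(col):
            levels = sorted(col.astype(str).unique())
            codes = {lvl: i + 1 for i, lvl in enumerate(levels)}
            level_maps[name] = {v: k for k, v in codes.items()}
            X[name] = col.astype(str).map(codes).astype(np.int64)
        else:
            X[name] = col.astype(np.int64 if kind != "count" else np.int64)
    w = df[config.treatment]
    if not pd.api.types.is_numeric_dtype(w) or not np.isin(w.unique(), [0, 1]).all():
        raise ValueError("treatment column must be binary 0/1")
    y = df[config.outcome]
    if not pd.api.types.is_numeric_dtype(y):
        raise ValueError("outcome column must be numeric")
    X = X.reset_index(drop=True)
    dataset = Dataset(X=X, W=w.to_numpy(), Y=y.to_numpy(dtype=float))
    return dataset, level_maps, n_dropped


def _stage_seeds(seed: int, names: Sequence[str]) -> Dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        name: int(child.generate_state(1)[0] >> 1)
        for name, child in zip(names, ss.spawn(len(names)))
    }


def run_analysis(config: RunConfig, force: bool = False) -> AnalysisReport:
    """Execute the full pipeline; deterministic for a fixed config+input."""
    seeds = _stage_seeds(
        config.seed, ["nuisance", "forest", "tree", "policy", "testing"]
    )
    dataset, level_maps, n_dropped = load_dataset(config.input, config)

    # --- nuisances + overlap gate ------------------------------------------
    learner = config.nuisance.get("learner", "rf")
    clip = tuple(config.nuisance.get("clip", [0.01, 0.99]))
    if learner == "truth":
        learner_config: object = "truth"
    else:
        learner_config = {
            "kind": learner,
            "n_estimators": config.nuisance.get("n_estimators", 200),
            "min_samples_leaf": config.nuisance.get("min_samples_leaf", 5),
        }
    nuis = fit_crossfit_nuisances(
        dataset,
        K=int(config.nuisance.get("folds", 5)),
        learner_config=learner_config,
        seed=seeds["nuisance"],
        clip_bounds=clip,
    )
    overlap = overlap_diagnostics(nuis.phat)
    overlap["n_clipped"] = nuis.n_clipped
    overlap["clip_share"] = nuis.n_clipped / dataset.n
    max_clip_share = float(config.overlap.get("max_clip_share", 0.1))
    violated = (not overlap["overlap_ok"]) or overlap["clip_share"] > max_clip_share
    overlap["violated"] = bool(violated)
    if violated and not force:
        raise OverlapError(
            f"positivity diagnostic failed (min={overlap['min']:.4f}, "
            f"max={overlap['max']:.4f}, clipped share="
            f"{overlap['clip_share']:.3f} > {max_clip_share}); "
            "rerun with force=True to continue anyway"
        )

    # --- scores and ATE -----------------------------------------------------
    scores = compute_scores(dataset, nuis)
    ate = ate_aipw(scores)
    naive = ate_diff_means(dataset)
    balance = balance_table(dataset, nuis.phat)

    # --- forest, OOB, calibration ------------------------------------------
    fcfg = ForestConfig(
        B=int(config.forest.get("B", 200)),
        subsample_fraction=float(config.forest.get("subsample_fraction", 0.5)),
        mtry=config.forest.get("mtry"),
        min_leaf=int(config.forest.get("min_leaf", 20)),
        max_depth=int(config.forest.get("max_depth", 4)),
        seed=seeds["forest"],
    )
    forest = fit_forest(dataset, scores, fcfg)
    oob = predict_oob(forest, dataset)
    importance = variable_importance(forest)
    calib = calibration_test(scores.effect_score, oob, seed=seeds["testing"])

    # --- pre-specified subgroups -------------------------------------------
    n_boot = int(config.testing.get("n_boot", 1000))
    subgroup_tables: Dict[str, pd.DataFrame] = {}
    subgroup_report: Dict[str, object] = {}
    for col in config.testing.get("groups", []):
        labels = dataset.X[col].to_numpy()
        cates = group_cate(scores.effect_score, labels)
        if len(cates) < 2:
            continue
        tab = pairwise_tests(cates)
        tab = adjust_pvalues(
            tab,
            "romano_wolf",
            effect_score=scores.effect_score,
            groups=labels,
            n_boot=n_boot,
            seed=seeds["testing"],
        )
        tab.insert(0, "grouping", col)
        subgroup_tables[col] = tab
        subgroup_report[col] = {
            "cates": [
                {"group": int(c.group), "tau_hat": c.tau_hat, "se": c.se, "n": c.n}
                for c in cates
            ],
            "tests": tab.drop(columns=["grouping"]).to_dict(orient="records"),
        }

    # --- honest causal tree + leaf contrasts --------------------------------
    tree_model = fit_causal_tree(
        dataset.X,
        dataset.W,
        scores.y_aipw,
        scores.effect_score,
        seed=seeds["tree"],
        min_leaf=int(config.tree.get("min_leaf", 50)),
        max_depth=int(config.tree.get("max_depth", 3)),
    )
    leaf_tests = leaf_heterogeneity_report(
        tree_model,
        dataset.X,
        scores.effect_score,
        n_boot=n_boot,
        seed=seeds["testing"],
    )

    # --- policy comparison ---------------------------------------------------
    depths = [int(d) for d in config.policy.get("depths", [1, 2])]
    policy_table = evaluate_policies(
        scores,
        dataset.X,
        dataset.W,
        oob_cate=oob,
        direction=config.direction,
        depths=depths,
        threshold_grid=int(config.policy.get("threshold_grid", 20)),
        split_seed=seeds["policy"],
    )

    dot: Dict[str, str] = {"causal_tree": render_dot(tree_model, level_maps, "causal_tree")}
    policy_trees_text: Dict[str, str] = {}
    for depth in depths:
        pol = fit_policy_tree(
            dataset.X,
            scores,
            depth=depth,
            direction=config.direction,
            threshold_grid=int(config.policy.get("threshold_grid", 20)),
            seed=seeds["policy"],
        )
        dot[f"policy_depth_{depth}"] = render_dot(pol.tree, level_maps, f"policy_depth_{depth}")
        policy_trees_text[f"depth_{depth}"] = render_tree_text(pol.tree, level_maps)

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.hash(),
            "n_rows": dataset.n,
            "n_dropped_missing": n_dropped,
            "n_treated": dataset.n_treated,
        },
        "ate": {
            "aipw": {"estimate": ate.estimate, "se": ate.se, "ci95": list(ate.ci95)},
            "diff_means": {
                "estimate": naive.estimate,
                "se": naive.se,
                "ci95": list(naive.ci95),
            },
        },
        "overlap": overlap,
        "calibration": {
            "alpha_hat": calib.alpha_hat,
            "beta_hat": calib.beta_hat,
            "se_alpha": calib.se_alpha,
            "se_beta": calib.se_beta,
            "p_beta_one_sided": calib.p_beta_one_sided,
            "heterogeneity_detected": calib.heterogeneity_detected,
        },
        "subgroups": subgroup_report,
        "tree": {
            "n_leaves": tree_model.n_leaves,
            "text": render_tree_text(tree_model, level_maps),
            "leaves": [
                {
                    "leaf_id": leaf.leaf_id,
                    "tau_hat": leaf.tau_hat,
                    "se": leaf.se,
                    "n_est": leaf.n_est,
                }
                for leaf in tree_model.root.leaves()
            ],
            "leaf_tests": leaf_tests.drop(columns=["note"], errors="ignore").to_dict(
                orient="records"
            ),
        },
        "policy": {
            "direction": config.direction,
            "comparison": policy_table.to_dict(orient="records"),
            "trees_text": policy_trees_text,
        },
        "importance": importance,
    }

    tables = {
        "ate": pd.DataFrame(
            [
                {"method": "aipw", "estimate": ate.estimate, "se": ate.se},
                {"method": "diff_means", "estimate": naive.estimate, "se": naive.se},
            ]
        ),
        "balance": balance,
        "leaf_tests": leaf_tests,
        "policy_comparison": policy_table,
        "importance": pd.DataFrame(
            [{"covariate": k, "weight": v} for k, v in importance.items()]
        ),
    }
    if subgroup_tables:
        tables["subgroups"] = pd.concat(subgroup_tables.values(), ignore_index=True)
    return AnalysisReport(report=report, tables=tables, dot=dot)


REQUIRED_REPORT_SECTIONS = (
    "provenance",
    "ate",
    "overlap",
    "calibration",
    "subgroups",
    "tree",
    "policy",
    "importance",
)


def validate_report(report: Dict) -> None:
    """Light structural check that every report section is present."""
    for key in REQUIRED_REPORT_SECTIONS:
        if key not in report:
            raise ValueError(f"report is missing section {key!r}")
    for method in ("aipw", "diff_means"):
        if "estimate" not in report["ate"][method]:
            raise ValueError(f"ate.{method} lacks an estimate")


def write_report(result: AnalysisReport, outdir: str) -> List[str]:
    """Write report.json, the CSV tables and the DOT renderings."""
    validate_report(result.report)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[str] = []
    report_path = out / "report.json"
    report_path.write_text(json.dumps(result.report, sort_keys=True, indent=2) + "\n")
    written.append(str(report_path))
    for name, table in result.tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(str(p))
    for name, dot in result.dot.items():
        p = out / f"{name}.dot"
        p.write_text(dot)
        written.append(str(p))
    return written
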