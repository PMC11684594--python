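"""Core in-memory containers shared by every stage of the pipeline.

A :class:`Dataset` is one row per individual: an integer-coded covariate
table ``X``, a binary treatment vector ``W`` and a continuous outcome ``Y``.
Synthetic datasets additionally carry the generating truth (propensity,
per-unit effect, both potential outcomes and the noiseless baseline), which
downstream code uses for oracle-mode nuisances and recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class GroundTruth:
    """Generator-side quantities that are unobservable in real data."""

    propensity: np.ndarray  # e(X), clamped inside (0, 1)
    cate: np.ndarray  # tau(X) = Y(1) - Y(0), exact per unit
    y0: np.ndarray  # potential outcome under control
    y1: np.ndarray  # potential outcome under treatment
    mu0: np.ndarray  # noiseless baseline E[Y(0) | X]

    def __post_init__(self) -> None:
        n = len(self.propensity)
        for name in ("cate", "y0", "y1", "mu0"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"truth field {name!r} has inconsistent length")


@dataclass
class Dataset:
    """Observational sample: covariates, binary treatment, scalar outcome."""

    X: pd.DataFrame
    W: np.ndarray
    Y: np.ndarray
    truth: Optional[GroundTruth] = field(default=None)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W)
        self.Y = np.asarray(self.Y, dtype=float)
        if len(self.X) != len(self.W) or len(self.X) != len(self.Y):
            raise ValueError("X, W and Y must have equal length")
        w = np.unique(self.W)
        if not np.isin(w, [0, 1]).all():
            raise ValueError("treatment W must be coded 0/1")
        self.W = self.W.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_treated(self) -> int:
        return int(self.W.sum())

    @property
    def n_control(self) -> int:
        return int(self.n - self.W.sum())

    def covariate_matrix(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)
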