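import numpy as np
import pandas as pd
import pytest

import drcate as dc


@pytest.fixture(scope="session")
def toy_scores():
    """Hand-computable 4-row sample: mu=0, p=0.5, (W,Y) = (1,3),(1,5),(0,1),(0,2)."""
    ds = dc.Dataset(
        X=pd.DataFrame({"x": [1, 2, 3, 4]}),
        W=np.array([1, 1, 0, 0]),
        Y=np.array([3.0, 5.0, 1.0, 2.0]),
    )
    nuis = dc.NuisanceEstimates(
        mu0=np.zeros(4),
        mu1=np.zeros(4),
        phat=np.full(4, 0.5),
        clip_bounds=(0.01, 0.99),
        n_clipped=0,
        folds=None,
    )
    return ds, dc.compute_scores(ds, nuis)


@pytest.fixture(scope="session")
def step_data():
    """One step-scenario dataset with oracle nuisance scores."""
    ds = dc.generate_dataset(dc.nhs_step_config(n=4000, seed=11))
    scores = dc.compute_scores(ds, dc.fit_crossfit_nuisances(ds, learner_config="truth"))
    return ds, scores


def oracle_step_scores(n: int, seed: int):
    ds = dc.generate_dataset(dc.nhs_step_config(n=n, seed=seed))
    scores = dc.compute_scores(ds, dc.fit_crossfit_nuisances(ds, learner_config="truth"))
    return ds, scores


def oracle_constant_scores(n: int, seed: int, tau: float = -1.0):
    ds = dc.generate_dataset(
        dc.DGPConfig(n=n, seed=seed, effect_spec=dc.ConstantEffect(tau))
    )
    scores = dc.compute_scores(ds, dc.fit_crossfit_nuisances(ds, learner_config="truth"))
    return ds, scores
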