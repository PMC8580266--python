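import numpy as np
import pandas as pd
import pytest

import bayimp as bi


@pytest.fixture(scope="session")
def desk_truth():
    return bi.multicentre_preset("desk", seed=11)


@pytest.fixture(scope="session")
def desk_data(desk_truth):
    ds, realized = bi.simulate_multilevel(desk_truth)
    return ds, realized


@pytest.fixture(scope="session")
def desk_analysis_spec(desk_truth):
    return bi.AnalysisSpec(
        outcome="y",
        outcome_family="continuous",
        covariates=[bi.Covariate(c.name, "random") for c in desk_truth.covariates],
    )


def small_dataset(seed=0, J=4, n_per=40, miss_rate=0.0):
    """A light two-covariate multilevel set for fast sampler tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(J):
        alpha = 1.0 + 0.4 * rng.standard_normal()
        x1 = rng.standard_normal(n_per)
        x2 = (rng.random(n_per) < 0.5).astype(float)
        y = alpha + 0.8 * x1 - 0.6 * x2 + 0.9 * rng.standard_normal(n_per)
        rows.append(pd.DataFrame({"grp": j + 1, "x1": x1, "x2": x2, "y": y}))
    frame = pd.concat(rows, ignore_index=True)
    ds = bi.assign_roles(
        bi.MultilevelDataset.from_frame(frame),
        cluster_var="grp",
        types={"x1": "continuous", "x2": "binary", "y": "continuous"},
    )
    if miss_rate > 0:
        ds = bi.induce_sporadic(ds, miss_rate, variables=["x1", "x2"], seed=seed)
    return ds


@pytest.fixture()
def small_ds():
    return small_dataset(seed=3)


@pytest.fixture()
def small_spec():
    return bi.AnalysisSpec(
        outcome="y",
        outcome_family="continuous",
        covariates=[bi.Covariate("x1", "random"), bi.Covariate("x2", "fixed")],
    )
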