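"""Shared fixtures: synthetic scenarios, fitted models, tiny tables."""

import numpy as np
import pandas as pd
import pytest

import cellnp as cp


@pytest.fixture(scope="session")
def default_config():
    return cp.default_scenario()


@pytest.fixture(scope="session")
def truth_models(default_config):
    """Exact generator Gaussians for the standard low/high dose pair."""
    cfg = default_config
    out = {}
    for ct in ("WT", "KO"):
        out[(ct, "h0")] = cp.condition_truth(cfg, ct, 0.0052).as_gaussian()
        out[(ct, "h1")] = cp.condition_truth(cfg, ct, 50.0).as_gaussian()
    return out


@pytest.fixture(scope="session")
def small_wide_table():
    """Five WT cells at one condition, two time points, log-scale."""
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(5)],
            "cell_type": "WT",
            "dose": 0.2,
            "response_30": np.exp([0.1, 0.2, 0.3, 0.4, 0.5]),
            "response_240": np.exp([1.1, 1.2, 1.3, 1.4, 1.5]),
        }
    )
    table = cp.ResponseTable(data=df, layout="wide", times=(30.0, 240.0))
    return cp.log_transform(table)


@pytest.fixture()
def long_csv(tmp_path):
    path = tmp_path / "long.csv"
    path.write_text(
        "cell_id,cell_type,tnf_ng_ml,time_min,nfkb_au\n"
        "c1,WT,0.2,30,55.0\n"
        "c2,WT,0.2,30,60.5\n"
        "c3,KO,50,240,120.25\n"
    )
    return path


def gaussian(mean, cov):
    return cp.GaussianCondition(mean=np.atleast_1d(mean), cov=np.atleast_2d(cov))


@pytest.fixture(scope="session")
def equal_var_pair():
    """Canonical m=1, lam=1 pair: Z = 2X - 1 is Gaussian under both."""
    return cp.canonicalize(gaussian(0.0, 1.0), gaussian(1.0, 1.0))
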