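import warnings

import numpy as np
import pandas as pd
import pytest

import methylworm as mw


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_config():
    return mw.SimConfig(seed=1, n_proteins=30, n_sites=60, n_substrate_sites=12)


@pytest.fixture(scope="session")
def small_study(small_config):
    return mw.simulate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """Study at the default (paper-scale) conditions."""
    return mw.simulate_study(mw.SimConfig(seed=0))


def make_matrix(values, n_replicates=3, scale="log2"):
    """Matrix helper: values is an array (features x 3*n_replicates)."""
    design = mw.make_design(n_replicates)
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                      columns=design.index)
    return mw.AbundanceMatrix(df, design, scale)
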