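import numpy as np
import pandas as pd
import pytest

import petalnet as pn


@pytest.fixture(scope="session")
def study_config():
    """The reference synthetic study: 50 TFs, 30 structural genes,
    10 planted metabolites, 8 levels, replicate noise 0.1, seed 42."""
    return pn.SimConfig(n_tf=50, n_structural=30, n_metabolites=10, rng_seed=42, noise_sd=0.1)


@pytest.fixture(scope="session")
def study(study_config):
    return pn.generate_timecourse(study_config)


@pytest.fixture(scope="session")
def study_pipeline(study):
    return pn.run_pipeline(study)


@pytest.fixture(scope="session")
def noiseless():
    cfg = pn.SimConfig(n_tf=16, n_structural=8, n_metabolites=4, rng_seed=5, noise_sd=0.0)
    return pn.generate_timecourse(cfg)


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless):
    return pn.run_pipeline(noiseless)


@pytest.fixture
def samples12():
    return pn.make_sample_sheet(3)


def matrix_from(values, samples, prefix="F"):
    """Feature matrix helper: rows of ``values`` become features."""
    arr = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i + 1:03d}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=ids, columns=[s.sample_id for s in samples])
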