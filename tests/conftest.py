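import numpy as np
import pytest

import pcrerr as pe


@pytest.fixture(scope="session")
def standard_dataset():
    """One study-scale dataset from the standard scenario (errorless spectra)."""
    truth = pe.default_truth(seed=0)
    return pe.simulate_dataset(truth, N=100, N_P=423, seed=0)


@pytest.fixture(scope="session")
def standard_model(standard_dataset):
    ds = standard_dataset
    model = pe.fit_pcr(ds.X_cal, ds.y_cal, A=5)
    return pe.calibrate_uncertainty(model, ds.X_cal, ds.y_cal)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_full_rank(rng):
    """Small full-rank instance (K < N) where the OLS formula applies."""
    N, K = 20, 5
    X = rng.standard_normal((N, K))
    y = X @ rng.standard_normal(K) + rng.standard_normal(N)
    return X, y
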