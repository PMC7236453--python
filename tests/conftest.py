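import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def clinical_table():
    """Small hand-written clinical table covering every labelling branch."""
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(8)],
            "os_days": [400.0, 400.0, 2000.0, 1100.0, 100.0, 1095.0, 3000.0, 50.0],
            "vital_status": ["dead", "alive", "alive", "dead", "dead", "dead", "alive", "dead"],
            "tumor_stage": ["Stage IIIA", "Stage I", "stage iv", "Stage IIB", None,
                             "Stage II", "Stage III", "not reported"],
        }
    )


@pytest.fixture
def separable_dataset(rng):
    """Samples x genes matrix with a strong multiplicative class effect.

    The first 20 genes are shifted up in class 1 strongly enough that a
    logistic model on those genes alone is nearly perfect.
    """
    n, p, k = 200, 128, 20
    y = np.concatenate([np.zeros(n // 2, int), np.ones(n - n // 2, int)])
    X = np.exp(rng.normal(2.0, 0.5, size=(n, p)))
    X[:, :k] *= np.exp(1.2 * y)[:, None]
    perm = rng.permutation(n)
    return X[perm], y[perm]


def make_surv(rng, n, beta, censor_scale=2.0):
    """One-covariate proportional-hazards draw used across survival tests."""
    z = rng.normal(size=n)
    T = rng.exponential(np.exp(-beta * z))
    C = rng.uniform(0, censor_scale, n)
    return z, np.minimum(T, C), (T <= C).astype(int)
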