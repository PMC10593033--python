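import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def assert_monotone_objective(fit, atol=1e-6):
    """The IBSS variational objective must be non-decreasing across sweeps."""
    trace = np.asarray(fit.objective_trace)
    diffs = np.diff(trace)
    scale = 1.0 + np.abs(trace[:-1])
    assert np.all(diffs >= -atol * scale), (
        f"objective decreased: min step {diffs.min():.3e} in {trace}"
    )


@pytest.fixture
def toy_regression(rng):
    """Small dense regression with two well-separated strong signals."""
    n, p = 200, 8
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[1], beta[6] = 0.8, -0.6
    y = X @ beta + rng.standard_normal(n)
    return X, y, np.array([1, 6])
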