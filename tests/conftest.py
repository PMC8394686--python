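import numpy as np
import pytest

import gcnet as g


@pytest.fixture(scope="session")
def bivariate_var1():
    """Stationary bivariate VAR(1) with a single strong edge X1 -> X2."""
    return g.VARModel(
        A=np.array([[[0.5, 0.0], [0.6, 0.3]]]),
        Sigma=np.eye(2),
    )


@pytest.fixture(scope="session")
def bivariate_panel(bivariate_var1):
    return g.simulate_var(bivariate_var1, 2000, seed=11)


@pytest.fixture(scope="session")
def white_panel():
    """Trivariate white noise, no dynamics at all."""
    model = g.VARModel(A=np.zeros((1, 3, 3)), Sigma=np.eye(3))
    return g.simulate_var(model, 1500, burn_in=10, seed=5)


@pytest.fixture(scope="session")
def benchmark_fit():
    panel = g.benchmark_panel(T=2000, seed=101)
    return g.fit_var(panel, 2)
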