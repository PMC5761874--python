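import numpy as np
import pytest

import dynconn as dc


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream, so assertions
    # on drawn data cannot depend on which other tests ran before
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def garch_null_spec():
    """White-noise bivariate spec (no ARMA, no GARCH dynamics, rho=0)."""
    return dc.SimulationSpec(T=2000, correlation=dc.ConstantCorrelation(0.0),
                             seed=0)


@pytest.fixture(scope="session")
def random_dfc_series():
    """20 random dFC-like trajectories in (-1, 1) for oracle comparisons."""
    rng = np.random.default_rng(20240917)
    out = []
    for _ in range(20):
        T = int(rng.integers(200, 460))
        x = np.tanh(np.cumsum(rng.standard_normal(T)) * 0.05
                    + 0.3 * rng.standard_normal(T))
        out.append(dc.DFCSeries(x, tr=2.0))
    return out


@pytest.fixture(scope="session")
def fitted_sinusoid():
    """One full two-step fit on a sinusoidal-truth subject (shared)."""
    spec = dc.SimulationSpec(T=450,
                             correlation=dc.SinusoidCorrelation(0.6, 0.01, 0.0),
                             seed=7)
    sub = dc.simulate_subject(spec)
    dfc, fits, dcc_fit = dc.estimate_dfc(sub.series)
    return sub, dfc, fits, dcc_fit
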