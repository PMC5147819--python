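import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lymphangion as ly

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Baseline parameters at low transmural pressure (100 Pa)."""
    return ly.ModelParameters()


@pytest.fixture(scope="session")
def params500():
    """Baseline parameters at high transmural pressure (500 Pa)."""
    return ly.ModelParameters(p_m=500.0)


@pytest.fixture(scope="session")
def eq100(params):
    return ly.equilibrium_radius(params)


@pytest.fixture(scope="session")
def eq500(params500):
    return ly.equilibrium_radius(params500)


def random_feasible_params(rng, **overrides):
    """Draw a random feasible parameter set around the baseline values."""
    while True:
        d = dict(
            p_m=float(rng.uniform(100.0, 1000.0)),
            a=float(2.45e4 * rng.uniform(0.5, 2.0)),
            A=float(12.3 * rng.uniform(0.5, 2.0)),
            p_offset=float(100.0 * rng.uniform(0.5, 2.0)),
            D=float(3e6 * rng.uniform(0.5, 2.0)),
            F_Ca=float(100.0 * rng.uniform(0.5, 2.0)),
            S_NO=float(3e-3 * rng.uniform(0.5, 2.0)),
            K_Ca=float(rng.uniform(0.5, 2.0)),
            K_NO=float(5.0 * rng.uniform(0.5, 2.0)),
            alpha=float(rng.uniform(0.05, 1.0)),
        )
        d.update(overrides)
        p = ly.ModelParameters(**d)
        # positive equilibrium radius requires the log argument above 1
        arg = (d["p_offset"] - p.F_Ca * p.S_Ca0 / p.K_Ca + d["p_m"]) / d["A"]
        if arg > 1.05:
            return p


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
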