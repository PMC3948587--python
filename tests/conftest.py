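import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from twodeme import ModelParameters, SelectionRegime

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def sel_weak_a() -> SelectionRegime:
    """Locus B under stronger selection in both demes (theta = 1)."""
    return SelectionRegime(0.5, -1.0, 2.0, -2.0)


@pytest.fixture
def sel_crossed() -> SelectionRegime:
    """Each locus under stronger selection in one deme (theta = 3.84)."""
    return SelectionRegime(0.4, -2.0, 2.0, -0.4)


@pytest.fixture
def params_weak_a(sel_weak_a) -> ModelParameters:
    return ModelParameters.create(0.5, -1.0, 2.0, -2.0, m=1.0, phi=0.375, rho=1.0)


def random_canonical_params(
    rng: np.random.Generator,
    *,
    rho: float | str = 1.0,
    m_high: float = 1.0,
) -> ModelParameters:
    """One random canonical parameter draw (log-uniform magnitudes)."""
    while True:
        mags = np.exp(rng.uniform(np.log(0.05), np.log(2.0), size=4))
        m = rng.uniform(0.0, m_high)
        phi = rng.uniform(0.0, 1.0)
        try:
            return ModelParameters.create(
                mags[0], -mags[1], mags[2], -mags[3], m=m, phi=phi, rho=rho
            )
        except ValueError:
            continue
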