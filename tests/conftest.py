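"""Shared fixtures: calibrated surface, surrogate runs and fitted results.

The heavier Langevin runs are session-scoped so the kinetics, decomposition
and acceptance tests share one realization per seed.
"""

import numpy as np
import pytest

from protonspec.model import ProtonTransferModel
from protonspec.surrogate import (
    LangevinConfig,
    SurfaceParams,
    build_surface,
    simulate_langevin,
)


@pytest.fixture(scope="session")
def surface() -> SurfaceParams:
    return build_surface()


@pytest.fixture(scope="session")
def medium_run(surface):
    """300k-step default-parameter run (~75 ps), enough for path statistics."""
    return simulate_langevin(surface, LangevinConfig(n_steps=300_000, seed=11))


@pytest.fixture(scope="session")
def medium_results(medium_run):
    return ProtonTransferModel.from_surrogate(medium_run).fit()


@pytest.fixture(scope="session")
def long_run(surface):
    """10^6-step default run used by the identity and calibration checks."""
    return simulate_langevin(surface, LangevinConfig(n_steps=1_000_000, seed=101))


@pytest.fixture(scope="session")
def long_results(long_run):
    return ProtonTransferModel.from_surrogate(long_run).fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
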