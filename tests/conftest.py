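import numpy as np
import pytest

from pulmo1d.solver import SimulationConfig
from pulmo1d.synthetic import TreeGenConfig, generate_inflow, generate_tree
from pulmo1d.wall import ConstitutiveParams, WallGeometry


@pytest.fixture(scope="session")
def control_params() -> ConstitutiveParams:
    """Wall constants fitted to healthy rat MPA tissue."""
    return ConstitutiveParams(c=10.0, k1=100.2, k2=5.3, beta=48.2)


@pytest.fixture(scope="session")
def ph_params() -> ConstitutiveParams:
    """Wall constants fitted to pulmonary-hypertensive rat MPA tissue."""
    return ConstitutiveParams(c=20.0, k1=310.0, k2=15.2, beta=46.2)


@pytest.fixture(scope="session")
def mpa_geom() -> WallGeometry:
    return WallGeometry.from_ratio(0.2, 0.10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_tree():
    """Two-generation symmetric tree (3 segments)."""
    return generate_tree(TreeGenConfig(n_generations=2))


@pytest.fixture(scope="session")
def rat_inflow():
    return generate_inflow()


@pytest.fixture(scope="session")
def fast_config() -> SimulationConfig:
    """Warm-started configuration used by the simulation tests."""
    return SimulationConfig(warm_start=True, cfl=0.8)
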