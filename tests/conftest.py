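import pytest

from cofba.config import BACTERIUM_KINETICS, YEAST_KINETICS
from cofba.dynamics import SimulationConfig
from cofba.model_io import load_alias_map
from cofba.synthetic_data import (bacterium_toy_spec, make_toy_model,
                                  toy_coculture, yeast_toy_spec)


@pytest.fixture(scope="session")
def alias_map():
    return load_alias_map()


@pytest.fixture(scope="session")
def toy_yeast():
    """Default glucose-only toy model and its closed-form oracle."""
    return make_toy_model(yeast_toy_spec())


@pytest.fixture(scope="session")
def toy_bact():
    """Default xylose-only toy model (with succinate branch, 14 reactions)."""
    return make_toy_model(bacterium_toy_spec())


@pytest.fixture(scope="session")
def toy_bact_small():
    """Succinate-free bacterium variant within the vertex-enumeration bound."""
    spec = bacterium_toy_spec(product_branches=(
        ("ethanol", 5.0 / 6.0), ("acetate", 5.0 / 6.0), ("formate", 5.0 / 3.0)))
    return make_toy_model(spec)


@pytest.fixture()
def coculture_pair():
    """Species pair under the standard operating conditions."""
    yeast, bact, oracles = toy_coculture()
    return yeast, bact, oracles


@pytest.fixture()
def base_conf():
    """The 50/50 mixture batch configuration."""
    return SimulationConfig(t_f=14.0, t_s=7.8, glucose_0=37.5, xylose_0=37.5)


@pytest.fixture()
def short_conf():
    """A cut-down batch for fast integration tests."""
    return SimulationConfig(t_f=4.0, t_s=2.0, glucose_0=37.5, xylose_0=37.5)
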