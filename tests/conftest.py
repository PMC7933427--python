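import numpy as np
import pytest

from dorsalcode.simulate import GeneExpression, PopulationSpec, SimulationConfig
from dorsalcode.studies import SPREAD_LAMINAE
from dorsalcode.template import default_template


@pytest.fixture(scope="session")
def template():
    return default_template()


def small_config(seed=0, n_cells=100, **overrides):
    """A light two-population config for unit tests."""
    mk = lambda p, m=12.0: GeneExpression(prob=p, mean_dots=m, dispersion=0.1)
    pops = [
        PopulationSpec("p1", 0.5, {"A": mk(0.9), "B": mk(0.3)}, SPREAD_LAMINAE),
        PopulationSpec("p2", 0.5, {"B": mk(0.8), "C": mk(0.9)}, SPREAD_LAMINAE),
    ]
    kwargs = dict(
        template=default_template(),
        populations=pops,
        n_cells=n_cells,
        n_animals=1,
        hemisections_per_animal=1,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture
def config():
    return small_config()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
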