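import numpy as np
import pytest

from feralscan.simulate import demo_params, simulate
from feralscan.variant_io import filter_sites


@pytest.fixture(scope="session")
def demo_sim():
    """One seeded run of the bundled study configuration (3 planted sweeps)."""
    params = demo_params(seed=1)
    sources, feral, table = simulate(params)
    return params, sources, feral, table


@pytest.fixture(scope="session")
def demo_table(demo_sim):
    """The observed, filtered site table of the demo run."""
    params, _, _, table = demo_sim
    return params, filter_sites(table)


@pytest.fixture(scope="session")
def null_sim():
    """A no-sweep run of the same configuration (null scan conditions)."""
    params = demo_params(seed=7, sweeps=False)
    sources, feral, table = simulate(params)
    return params, sources, feral, table


@pytest.fixture()
def rng():
    return np.random.default_rng(20160930)
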