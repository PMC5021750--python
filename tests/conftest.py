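import dataclasses

import pytest
from hypothesis import settings

import epagrowth as eg

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg():
    """The default 12-clone simulation scenario, seed 1."""
    return eg.default_config(seed=1)


@pytest.fixture(scope="session")
def growth_data(default_cfg):
    """One default growth dataset plus its clone table."""
    return eg.simulate_growth(default_cfg), list(default_cfg.clones)


@pytest.fixture(scope="session")
def small_cfg():
    """3 clones x 5 EPA levels x 2 replicates: fast mixed-model instances."""
    base = eg.default_config(seed=7)
    clones = (base.clones[2], base.clones[5], base.clones[9])  # spread of sizes
    return dataclasses.replace(
        base,
        clones=clones,
        epa_grid=(0.0, 0.5, 1.5, 4.0, 10.0),
        n_replicates=2,
    )


@pytest.fixture(scope="session")
def small_growth(small_cfg):
    return eg.simulate_growth(small_cfg), list(small_cfg.clones)
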