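import numpy as np
import pytest

import airdisparity as ad

# Full-scale study conditions: 200x200 grid, u = 5 m/s, H = 100 m,
# sigma = 40 cells, source at (150, 100), E from 10 g/s over 1000 steps.
FULL = dict(n=200, n_steps=1000, initial_emissions=10.0,
            source_start=(150.0, 100.0))

# Shrunken conditions for fast unit tests.
SMALL = dict(n=21, n_steps=50, initial_emissions=10.0,
             source_start=(15.0, 10.0), margin=2.0, sigma=4.0)


@pytest.fixture(scope="session")
def small_city():
    return ad.build_city(SMALL["n"])


@pytest.fixture(scope="session")
def small_params():
    return ad.DispersionParams(n_cells=SMALL["n"], sigma=SMALL["sigma"])


def _make_small(kind, city, params):
    return ad.make_scenario(kind, city, params, n_steps=SMALL["n_steps"],
                            initial_emissions=SMALL["initial_emissions"],
                            source_start=SMALL["source_start"],
                            margin=SMALL["margin"])


@pytest.fixture(scope="session")
def small_results(small_city, small_params):
    """All three scenarios at the shrunken scale."""
    return {
        kind: ad.run_scenario(small_city, _make_small(kind, small_city,
                                                      small_params),
                              small_params)
        for kind in ad.SCENARIO_KINDS
    }


@pytest.fixture(scope="session")
def full_city():
    return ad.build_city(FULL["n"])


@pytest.fixture(scope="session")
def full_params():
    return ad.DispersionParams()


@pytest.fixture(scope="session")
def full_results(full_city, full_params):
    """The three scenarios at full scale, conserved pollutant."""
    out = {}
    for kind in ad.SCENARIO_KINDS:
        spec = ad.make_scenario(kind, full_city, full_params,
                                n_steps=FULL["n_steps"],
                                initial_emissions=FULL["initial_emissions"],
                                source_start=FULL["source_start"])
        out[kind] = ad.run_scenario(full_city, spec, full_params)
    return out


@pytest.fixture(scope="session")
def full_results_decay(full_city, full_params):
    """The three scenarios at full scale with first-order loss enabled."""
    params = ad.DispersionParams(
        decay_rate=ad.default_decay_rate(full_params))
    out = {}
    for kind in ad.SCENARIO_KINDS:
        spec = ad.make_scenario(kind, full_city, params,
                                n_steps=FULL["n_steps"],
                                initial_emissions=FULL["initial_emissions"],
                                source_start=FULL["source_start"])
        out[kind] = ad.run_scenario(full_city, spec, params)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
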