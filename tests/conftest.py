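"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pytest

import headbody as hb


@pytest.fixture(scope="session")
def grid_e1_mc():
    return hb.make_stimulus_grid("E1", "P1", "MC")


@pytest.fixture(scope="session")
def monkey_grid_mc():
    """All 64 whole-monkey conditions, P1, monkey-centered."""
    return hb.monkey_conditions("P1", "MC")


@pytest.fixture(scope="session")
def tuned_unit(monkey_grid_mc):
    """One strongly tuned conjunctive unit over the full 8 x 8 grid."""
    params = hb.TuningParams(mu_head=90, mu_body=180, kappa_head=2.5,
                             kappa_body=2.5, w_conj=1.0, gain=60, baseline=10)
    return hb.simulate_unit(params, monkey_grid_mc, seed=7)


@pytest.fixture(scope="session")
def flat_unit(monkey_grid_mc):
    """An untuned, baseline-only unit (gain 0)."""
    return hb.simulate_unit(hb.TuningParams(gain=0.0, baseline=10.0),
                            monkey_grid_mc, seed=8)


@pytest.fixture(scope="session")
def conjunctive_pop_0180():
    """60 conjunctive units over the 0/180-degree angle conditions."""
    return hb.decoding_population(n_units=60, w_conj=1.0, seed=21)


@pytest.fixture(scope="session")
def additive_pop_0180():
    """60 rate-additive units over the 0/180-degree angle conditions."""
    return hb.decoding_population(n_units=60, w_conj=0.0, seed=22)
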