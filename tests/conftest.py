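"""Shared fixtures: simulated genome panels and small genomes.

Panels are session-scoped because genome simulation dominates suite
runtime; every test that needs the default selection-gradient panel
(40 genomes, S in [0, 5]) shares one realisation.
"""

import pytest

from codonbias import SimulationConfig, panel_configs, simulate_genome, simulate_panel

#: single global seed for every stochastic fixture in the suite
SEED = 11


@pytest.fixture(scope="session")
def panel_theta05():
    """40-genome panel, S equally spaced in [0, 5], theta = 0.5."""
    genomes, profiles = simulate_panel(panel_configs(40, theta=0.5, seed=SEED))
    return genomes, profiles


@pytest.fixture(scope="session")
def panel_theta09():
    """Same S grid at theta = 0.9 (GC-extreme panel)."""
    genomes, profiles = simulate_panel(panel_configs(40, theta=0.9, seed=SEED))
    return genomes, profiles


@pytest.fixture(scope="session")
def unbiased_genome():
    """Default-size genome with no translational selection (S = 0)."""
    return simulate_genome(SimulationConfig(seed=SEED, selection=0.0))


@pytest.fixture(scope="session")
def biased_genome():
    """Default-size genome under strong selection (S = 4)."""
    return simulate_genome(SimulationConfig(seed=SEED, selection=4.0))
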