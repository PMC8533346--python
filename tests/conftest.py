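"""Shared fixtures: session-scoped desk-profile ensembles.

The 100-trial ensembles mirror the published study conditions (10 s trials,
10 s burn-in, dt = 0.1 ms); the small bundles are for fast unit tests.
"""

import numpy as np
import pytest

from slowwave import calibrate, experiments
from slowwave.simulate import StimulusSpec

DESK = 100


@pytest.fixture(scope="session")
def nrem100():
    """Unstimulated one-column NREM ensemble, desk profile."""
    return experiments.simulate_state("nrem", trials=DESK, seed=101)


@pytest.fixture(scope="session")
def wake100():
    """Unstimulated one-column wake ensemble, desk profile."""
    return experiments.simulate_state("wake", trials=DESK, seed=102)


@pytest.fixture(scope="session")
def nrem_stim100():
    return experiments.simulate_state("nrem", stimulus=StimulusSpec(),
                                      trials=DESK, seed=103)


@pytest.fixture(scope="session")
def wake_stim100():
    return experiments.simulate_state("wake", stimulus=StimulusSpec(),
                                      trials=DESK, seed=104)


@pytest.fixture(scope="session")
def nrem_targets(nrem100):
    return calibrate.estimate_up_state_targets(nrem100)


@pytest.fixture(scope="session")
def unit_nrem():
    """Tiny NREM ensemble (8 trials x 2 s) for fast checks."""
    return experiments.simulate_state("nrem", trials=8, seed=7,
                                      trial_length=2.0, burn_in=2.0)
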