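import dataclasses

import numpy as np
import pytest

from tfbsc.conservation import call_conservation
from tfbsc.motif_scoring import PSSM
from tfbsc.synthetic_data import SimulationConfig, generate_bundle


@pytest.fixture()
def toy_pssm():
    """Two-column matrix favoring A then C (0.7 vs 0.1), uniform background."""
    probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1]])
    return PSSM("toy", probs)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated bundle shared by cross-module tests."""
    cfg = dataclasses.replace(
        SimulationConfig(),
        n_chromosomes=2, chromosome_length=100_000, n_tfs=10,
        n_genes=300, n_sites=800,
    )
    return generate_bundle(cfg, seed=1)


@pytest.fixture(scope="session")
def small_calls(small_sim):
    return call_conservation(small_sim.bundle, detect_gains=True)
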