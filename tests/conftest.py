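import math

import numpy as np
import pytest

import attention_swarm as asw

CRYSTAL_ALPHA = math.radians(75)


@pytest.fixture(scope="session")
def crystal_runs_p30():
    """Seeded runs of a 30-agent swarm (same density as the 91-agent
    default) in the ordered attention regime; most reach quasi-stationary
    crystal states within the sweep cap."""
    L = 1.74 * math.sqrt(30 / 91)
    trajs = []
    for seed in range(6):
        params = asw.SimulationParams(
            P=30, L=L, seed=seed, alpha=CRYSTAL_ALPHA, max_sweeps=100_000
        )
        trajs.append(asw.run(params))
    return trajs


@pytest.fixture(scope="session")
def fragmented_runs():
    """Twenty seeded runs at full attention field (global nearest
    neighbour); these freeze into fragmented configurations quickly."""
    trajs = []
    for rep in range(20):
        seed = asw.replicate_seed(1, 2 * math.pi, rep)
        params = asw.SimulationParams(seed=seed, alpha=2 * math.pi, max_sweeps=50_000)
        trajs.append(asw.run(params))
    return trajs
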