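import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from driftfold.chain_model import CoarseChain, PivotBond
from driftfold.forcefield import ForceFieldParams
from driftfold.residue_props import annotate_sequence


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams()


@pytest.fixture(scope="session")
def cold_params():
    return ForceFieldParams(temperature_K=0.0)


def random_chain(rng, n_sites, charged_fraction=0.6, box=2.0):
    """A random non-collinear coarse chain for force/torque checks."""
    positions = np.cumsum(rng.uniform(-0.4, 0.4, size=(n_sites, 3)), axis=0)
    positions += rng.uniform(-box, box, size=3)
    charges = np.where(
        rng.random(n_sites) < charged_fraction,
        rng.choice([-1.0, 1.0], size=n_sites) * rng.uniform(0.2, 1.0, n_sites),
        0.0,
    )
    hydro = rng.uniform(-4.5, 4.5, size=n_sites)
    return CoarseChain(
        positions=positions,
        charges=charges,
        hydrophobicity=hydro,
        spans=[(i, i) for i in range(n_sites)],
        rigid_group=np.full(n_sites, -1, dtype=int),
        pivots=[PivotBond(i) for i in range(n_sites - 1)],
    )


@pytest.fixture
def make_random_chain():
    return random_chain


@pytest.fixture(scope="session")
def helix_seq():
    """Annotated helix-forming fixture sequence (D-A-E bracket, pH 7)."""
    return annotate_sequence("AAAADAEAAAAA")
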