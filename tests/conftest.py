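import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles module

import pbflex as pf


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def prototypes():
    return pf.load_prototypes()


def letters_to_states(letters: str) -> np.ndarray:
    return np.array([[pf.PB_LABELS.index(c) for c in letters]], dtype=np.int8)


@pytest.fixture
def helix_ensemble():
    """10-residue, 4-frame ideal helix (all PB m, no noise)."""
    spec = pf.GeneratorSpec(n_residues=10, n_frames=4, base_letters="m" * 10)
    ens, states, truth = pf.generate_ensemble(spec, np.random.default_rng(3))
    return ens
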