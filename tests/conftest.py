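import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from kirblock import (
    SolutionCondition,
    StateModel,
    blocker_preset,
)
from kirblock.params import BlockerSpec


@pytest.fixture(scope="session")
def sym100():
    """Symmetric 100 mM K+ with blocker slots for Mg and SPM."""
    return SolutionCondition(100.0, 100.0, {"Mg": 0.0, "SPM": 0.0})


@pytest.fixture(scope="session")
def mg_wt():
    return blocker_preset("Mg", "WT")


@pytest.fixture(scope="session")
def spm_wt():
    return blocker_preset("SPM", "WT")


@pytest.fixture(scope="session")
def simple_blocker():
    """Plain two-state blocker with no flux coupling or punch-through."""
    return BlockerSpec(
        id="X", valence=2, kon0=2.0e6, delta_on=0.075, koff0=100.0, zdelta_off=0.5
    )


@pytest.fixture(scope="session")
def simple_model(simple_blocker):
    return StateModel([simple_blocker])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
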