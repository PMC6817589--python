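import numpy as np
import pytest

from tcrfingerprint import (
    PositionWeightMatrix,
    SyntheticScenario,
    make_kernel,
)
from tcrfingerprint.core import AA_INDEX, AMINO_ACIDS
from tcrfingerprint.fingerprint import scored_positions_for

EPITOPE = "SLLMWITQV"
ANCHORS = frozenset({2, 9})


def random_pwm(rng, epitope=EPITOPE, anchors=ANCHORS, assay="binding"):
    """A random valid PWM: uniform cells with epitope residues pinned at 100."""
    positions = scored_positions_for(epitope, anchors)
    weights = rng.uniform(0.0, 100.0, size=(20, len(positions)))
    for j, pos in enumerate(positions):
        weights[AA_INDEX[epitope[pos - 1]], j] = 100.0
    return PositionWeightMatrix(
        epitope=epitope, anchor_positions=anchors,
        scored_positions=positions, weights=weights, assay=assay,
    )


def random_peptide(rng, k=9):
    return "".join(rng.choice(list(AMINO_ACIDS), size=k))


@pytest.fixture
def epitope():
    return EPITOPE


@pytest.fixture
def anchors():
    return ANCHORS


@pytest.fixture
def kernel():
    return make_kernel(20191022, EPITOPE, ANCHORS, frozenset({5, 8}))


@pytest.fixture
def default_scenario():
    return SyntheticScenario()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
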