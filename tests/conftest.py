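import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from alulandscape import (
    AlignmentParams,
    SyntheticConfig,
    generate_background,
    generate_consensus_library,
    plant_copies,
)


@pytest.fixture(scope="session")
def library():
    """Two-family consensus library: one dimer-sized, one monomer-sized."""
    return generate_consensus_library([("AluY", 300), ("FLAM", 120)], seed=101)


@pytest.fixture(scope="session")
def planted_bundle(library):
    """A 40 kb host with 12 planted copies at zero divergence, plus truth."""
    background = generate_background(40_000, 0.45, seed=202)
    config = SyntheticConfig(
        background_length=40_000, n_copies=12, divergence=0.0, seed=303
    )
    host, truth = plant_copies(background, library, config)
    return host, truth


@pytest.fixture(scope="session")
def default_params():
    return AlignmentParams()
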