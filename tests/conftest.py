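import numpy as np
import pytest

from deltamol.chemdata import MoleculeRecord
from deltamol.synthdata import GeneratorConfig, generate_library


@pytest.fixture(scope="session")
def synth100():
    """100-molecule additive synthetic dataset, mild noise."""
    return generate_library(GeneratorConfig(n_molecules=100, noise_sd=0.1, seed=7))


@pytest.fixture(scope="session")
def synth50_clean():
    """50 molecules, zero noise: observed value equals the additive truth."""
    return generate_library(GeneratorConfig(n_molecules=50, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def records30(synth100):
    return synth100.dataset.records[:30]


@pytest.fixture
def toy_records():
    """Three hand-built molecules with simple values."""
    return [
        MoleculeRecord("a", "CCO", 1.0),
        MoleculeRecord("b", "CCN", 3.0),
        MoleculeRecord("c", "CCC", 2.5),
    ]
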