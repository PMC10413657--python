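import numpy as np
import pytest

from assembly_buffer import gen_globular_chain, gen_homodimer_structure


@pytest.fixture(scope="session")
def homodimer_mid():
    """50-residue homodimer with a central interface (residues 20-30)."""
    return gen_homodimer_structure(50, 0.5, 0.2, seed=7)


@pytest.fixture(scope="session")
def homodimer_cterm():
    """100-residue homodimer with a C-terminal interface (residues 90-100)."""
    return gen_homodimer_structure(100, 0.95, 0.1, seed=1)


@pytest.fixture(scope="session")
def linear_chain():
    """A single straight-ish chain of 200 residues (chain A of a dimer)."""
    return gen_homodimer_structure(200, 0.5, 0.2, seed=3).chains[0]


@pytest.fixture(scope="session")
def globular_chain():
    """Compact 200-residue globule with sequence-independent packing."""
    return gen_globular_chain(200, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
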