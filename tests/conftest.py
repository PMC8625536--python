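import numpy as np
import pytest

from ecph import fixtures as fx
from ecph.titration import TitratableSite


@pytest.fixture(scope="session")
def templates():
    return fx.make_residue_templates()


@pytest.fixture(scope="session")
def glu_peptide():
    """Capped Glu peptide structure + template library."""
    return fx.make_titratable_peptide("GLU", capped=True, seed=7)


@pytest.fixture(scope="session")
def solvated_glu():
    """Glu peptide in a 216-water lattice box."""
    return fx.make_solvated_peptide("GLU", n_waters=216, seed=11)


@pytest.fixture()
def glu_site():
    return TitratableSite("A", 1, "GLU")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
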