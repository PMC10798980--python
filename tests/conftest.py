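import numpy as np
import pytest

from godmd.structures import generate_toy_dimer
from godmd.topology import build_topology


@pytest.fixture(scope="session")
def toy_dimer():
    """A 30-residue-per-chain dimer with 6 spread interface pairs."""
    return generate_toy_dimer(30, 6, 0.5, [11, 62], seed=1)


@pytest.fixture(scope="session")
def toy_dimer_topology(toy_dimer):
    return build_topology(toy_dimer)


@pytest.fixture(scope="session")
def centered(toy_dimer):
    """Copy of the toy dimer centred in an 80 Å box."""
    import copy

    s = copy.deepcopy(toy_dimer)
    s.positions = s.positions - s.positions.mean(axis=0) + 40.0
    return s


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.134   7.440  -4.680  1.00  0.00           C
ATOM      4  C   ALA A   1      10.560   5.500  -4.200  1.00  0.00           C
ATOM      5  N   GLY A   2       9.900   4.600  -4.900  1.00  0.00           N
ATOM      6  CA  GLY A   2       8.800   3.800  -4.300  1.00  0.00           C
ATOM      7  C   GLY A   2       7.600   4.600  -3.900  1.00  0.00           C
ATOM      8  N   SER A   3       6.900   5.200  -4.800  1.00  0.00           N
ATOM      9  CA  SER A   3       5.700   6.000  -4.500  1.00  0.00           C
ATOM     10  CB  SER A   3       4.600   5.200  -3.800  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB
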