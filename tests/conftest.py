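import numpy as np
import pytest

from apis.geometry import GeometryParams
from apis.synthetic import helix_pair_partition, make_structure


@pytest.fixture(scope="session")
def params():
    return GeometryParams()


@pytest.fixture(scope="session")
def pair_model():
    return make_structure("helix_pair_complex")


@pytest.fixture(scope="session")
def pair_partition():
    return helix_pair_partition()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_pdb(tmp_path):
    """A tiny hand-written PDB exercising altlocs, HETATM, waters, hydrogens."""
    text = """\
ATOM      1  N   ASP A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ASP A   1      10.000   5.000  -6.000  1.00 12.00           C
ATOM      3  C   ASP A   1       9.000   5.500  -5.000  1.00 11.00           C
ATOM      4  O   ASP A   1       8.500   6.600  -5.200  1.00 13.00           O
ATOM      5  CB AASP A   1      10.500   3.800  -5.300  0.60 14.00           C
ATOM      6  CB BASP A   1      10.400   3.700  -5.200  0.40 15.00           C
ATOM      7  OD1 ASP A   1      11.800   3.000  -5.000  1.00 16.00           O
ATOM      8  H   ASP A   1      11.500   6.000  -7.000  1.00 10.00           H
ATOM      9  N   GLY A   2       8.700   4.700  -4.000  1.00  9.00           N
ATOM     10  CA  GLY A   2       7.700   5.000  -3.000  1.00  8.00           C
ATOM     11  C   GLY A   2       6.400   4.400  -3.500  1.00  7.50           C
ATOM     12  O   GLY A   2       6.300   3.200  -3.700  1.00  7.00           O
ATOM     13  N   CYS B   1       2.000   2.000   2.000  1.00 20.00           N
ATOM     14  CA  CYS B   1       3.000   2.500   2.800  1.00 21.00           C
ATOM     15  C   CYS B   1       4.300   1.800   2.500  1.00 22.00           C
ATOM     16  O   CYS B   1       4.400   0.600   2.700  1.00 23.00           O
ATOM     17  CB  CYS B   1       3.200   4.000   2.600  1.00 24.00           C
ATOM     18  SG  CYS B   1       2.000   5.000   3.500  1.00 25.00           S
ATOM     19  N   ALA B   2       5.300   2.500   2.000  1.00 26.00           N
ATOM     20  CA  ALA B   2       6.600   2.000   1.600  1.00 27.00           C
ATOM     21  C   ALA B   2       7.600   3.100   1.400  1.00 28.00           C
ATOM     22  O   ALA B   2       7.400   4.200   1.900  1.00 29.00           O
ATOM     23  CB  ALA B   2       6.500   1.200   0.300  1.00 30.00           C
TER
HETATM   24  ZN  ZN  A 101       0.000   0.000   0.000  1.00 30.00          ZN
HETATM   25  O   HOH A 102       1.000   1.000   1.000  1.00 30.00           O
END
"""
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path
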