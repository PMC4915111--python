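import numpy as np
import pytest

from pssm.simulate import make_synthetic_structure, random_rotation

# A tiny 3-residue PDB with backbone + side-chain atoms, one altloc pair,
# a hydrogen, a water and a second model — exercises every read_pdb rule.
PDB_FIXTURE = """\
HEADER    SYNTHETIC TEST STRUCTURE
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.707   6.859  -4.240  1.00  0.00           C
ATOM      4  O   ALA A   1       9.855   7.611  -4.705  1.00  0.00           O
ATOM      5  CB  ALA A   1      13.070   6.550  -5.118  1.00  0.00           C
ATOM      6  H   ALA A   1      10.995   5.500  -7.100  1.00  0.00           H
ATOM      7  N   SER A   2      10.872   6.701  -2.929  1.00  0.00           N
ATOM      8  CA ASER A   2      10.030   7.404  -1.951  0.50  0.00           C
ATOM      9  CA BSER A   2      10.031   7.405  -1.950  0.50  0.00           C
ATOM     10  C   SER A   2      10.513   7.206  -0.524  1.00  0.00           C
ATOM     11  O   SER A   2      11.638   6.757  -0.298  1.00  0.00           O
ATOM     12  OG  SER A   2       8.683   6.921  -2.055  1.00  0.00           O
ATOM     13  N   GLY A   3       9.650   7.551   0.437  1.00  0.00           N
ATOM     14  CA  GLY A   3      10.002   7.420   1.846  1.00  0.00           C
ATOM     15  C   GLY A   3       9.091   8.251   2.737  1.00  0.00           C
ATOM     16  O   GLY A   3       8.070   8.771   2.281  1.00  0.00           O
TER      17      GLY A   3
HETATM   18  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      99.000  99.000  99.000  1.00  0.00           N
ENDMDL
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    path = tmp_path / "fixture.pdb"
    path.write_text(PDB_FIXTURE)
    return path


@pytest.fixture
def helix108():
    return make_synthetic_structure(108, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cloud(rng, n=30, scale=10.0):
    return rng.normal(scale=scale, size=(n, 3))


@pytest.fixture
def rotated_pair(helix108):
    rot = random_rotation(7)
    return helix108, helix108.transformed(rot), rot
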