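import numpy as np
import pytest

import protfuse as pf

# handwritten 3-residue chain (ALA, CYS, ASP), 5 heavy atoms each, wwPDB
# fixed-width columns
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   CYS A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  CYS A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   CYS A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   CYS A   2       6.030   1.581   0.000  1.00  0.00           O
ATOM     10  SG  CYS A   2       3.401   3.702   1.472  1.00  0.00           S
ATOM     11  N   ASP A   3       6.191   3.829   0.000  1.00  0.00           N
ATOM     12  CA  ASP A   3       7.646   3.839   0.000  1.00  0.00           C
ATOM     13  C   ASP A   3       8.219   5.249   0.000  1.00  0.00           C
ATOM     14  O   ASP A   3       7.459   6.222   0.000  1.00  0.00           O
ATOM     15  CB  ASP A   3       8.182   3.072  -1.216  1.00  0.00           C
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "acd.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def helix10():
    return pf.make_helix(10, 0.0, 7)


@pytest.fixture
def noisy_helix():
    return pf.make_helix(30, 0.3, 11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng) -> pf.RigidTransform:
    """Haar-uniform rotation + uniform translation in a 20 A box."""
    from protfuse.point_autoencoder import random_rotation

    R = random_rotation(int(rng.integers(2**31)))
    t = rng.uniform(-10.0, 10.0, size=3)
    return pf.RigidTransform(R, t)
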