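import numpy as np
import pytest

from confdiff.synthetic_structures import BackboneSpec, build_backbone

# hand-written 3-residue PDB (backbone + CB), used by the parsing tests
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.922  1.00 10.00           C
ATOM      4  O   ALA A   1      13.825   7.031  -5.374  1.00 10.00           O
ATOM      5  CB  ALA A   1      10.530   6.188  -4.109  1.00 10.00           C
ATOM      6  N   ALA A   2      12.295   8.233  -4.240  1.00 10.00           N
ATOM      7  CA  ALA A   2      13.204   9.359  -4.003  1.00 10.00           C
ATOM      8  C   ALA A   2      13.751   9.911  -5.317  1.00 10.00           C
ATOM      9  O   ALA A   2      14.938  10.234  -5.419  1.00 10.00           O
ATOM     10  CB  ALA A   2      12.477  10.461  -3.233  1.00 10.00           C
ATOM     11  N   ALA A   3      12.893  10.022  -6.329  1.00 10.00           N
ATOM     12  CA  ALA A   3      13.290  10.540  -7.635  1.00 10.00           C
ATOM     13  C   ALA A   3      14.322   9.621  -8.281  1.00 10.00           C
ATOM     14  O   ALA A   3      15.298   10.091  -8.872  1.00 10.00           O
ATOM     15  CB  ALA A   3      12.073  10.708  -8.543  1.00 10.00           C
TER      16      ALA A   3
END
"""

# one atom with two alternate locations (A occ 0.6 / B occ 0.4)
ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  OG ASER A   1       2.000  -1.000   1.000  0.60 10.00           O
ATOM      6  OG BSER A   1       2.000  -1.000  -1.000  0.40 10.00           O
END
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_RESIDUE_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def helix20():
    """Ideal 20-residue alpha-helix built at phi=-57, psi=-47, omega=180."""
    return build_backbone(BackboneSpec.uniform(20, phi=-57.0, psi=-47.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
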