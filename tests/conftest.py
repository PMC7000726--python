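import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Hand-built coordinate file exercising the parsing policies: altLocs,
# multiple models, HETATM amino acid (MSE), water, metal ion, an
# unknown ATOM-record residue, and a resolution header.
TINY_PDB = """\
REMARK   2 RESOLUTION.    1.10 ANGSTROMS.
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.40  0.00           C
ATOM      3  CA BALA A   1      11.700   6.100  -5.200  0.60  0.00           C
ATOM      4  C   ALA A   1      10.674   6.719  -4.147  1.00  0.00           C
HETATM    5  N   MSE A   2       9.903   7.742  -4.539  1.00  0.00           N
HETATM    6  CA  MSE A   2       8.938   8.390  -3.639  1.00  0.00           C
HETATM    7  C   MSE A   2       9.000   9.900  -3.800  1.00  0.00           C
ATOM      8  N   GLY A   3       9.500  10.500  -2.800  1.00  0.00           N
ATOM      9  CA  GLY A   3       9.600  11.900  -2.700  1.00  0.00           C
ATOM     10  C   GLY A   3      10.900  12.400  -2.100  1.00  0.00           C
ATOM     11  N   XYZ A   4      11.500  13.000  -1.500  1.00  0.00           N
ATOM     12  CA  XYZ A   4      12.500  13.500  -1.000  1.00  0.00           C
HETATM   13  O   HOH A 101       5.000   5.000   5.000  1.00  0.00           O
HETATM   14 MG    MG A 102       4.000   4.000   4.000  1.00  0.00          MG
ENDMDL
MODEL        2
ATOM     15  N   ALA A   1      99.000  99.000  99.000  1.00  0.00           N
ENDMDL
END
"""


@pytest.fixture
def tiny_pdb_path(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def tiny_structure(tiny_pdb_path):
    from exstab.io import read_pdb

    return read_pdb(tiny_pdb_path)
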