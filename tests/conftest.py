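import pytest

from pepbind.energetics import PBSettings
from pepbind.synthetic import EnsembleSpec, make_ensemble, make_toy_complex

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.040  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
TER
ATOM      5  N   SER B   1       0.000   0.000   4.000  1.00  0.00           N
ATOM      6  CA  SER B   1       1.458   0.000   4.000  1.00  0.00           C
ATOM      7  OG  SER B   1       2.000   1.300   4.000  1.00  0.00           O
TER
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.558   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""


@pytest.fixture
def three_atom_path(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return str(p)


@pytest.fixture
def two_chain_path(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return str(p)


@pytest.fixture
def two_model_path(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return str(p)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(4, 4, 4.0, seed=1, seq_a="ARLS", seq_b="AELS")


@pytest.fixture(scope="session")
def toy_ensemble(toy_complex):
    return make_ensemble(
        toy_complex, EnsembleSpec(n_frames=3, per_atom_sigma=0.05, seed=11)
    )


@pytest.fixture(scope="session")
def fast_pb_settings():
    """Coarse but complete settings: full physics, desk-scale grid."""
    return PBSettings(grid_spacing=0.8, box_margin=5.0)


@pytest.fixture(scope="session")
def gas_settings():
    """Gas-phase + SASA only; PB switched off for speed."""
    return PBSettings(include_polar=False)
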