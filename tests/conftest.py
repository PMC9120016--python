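import numpy as np
import pytest

from dynevo import synthetic
from dynevo.ensemble import Ensemble
from dynevo.structio import Residue, Structure

TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.123   7.440  -4.699  1.00  0.00           C
ATOM      4  CA  GLY A   2      12.994   9.297  -3.217  1.00  0.00           C
ATOM      5  CA  SER A   3      14.324  11.289  -0.879  1.00  0.00           C
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def collinear_chain():
    """5 Cα on a line, 0.38 nm apart, single chain."""
    coords = np.array([[0.38 * i, 0.0, 0.0] for i in range(5)])
    residues = [Residue("A", i + 1, "", "A") for i in range(5)]
    return Structure(id="line", residues=residues, coords=coords)


@pytest.fixture(scope="session")
def tetramer():
    s, cmap, gt = synthetic.synth_structure(20, "tetramer", seed=0)
    return s, cmap, gt


@pytest.fixture(scope="session")
def monomer50():
    s, _, _ = synthetic.synth_structure(50, "monomer", seed=0)
    return s


def make_ensemble(structure, coords, seed=0):
    return Ensemble(topology=structure, coords=np.asarray(coords), seed=seed)
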