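import numpy as np
import pytest

from calyxpath import synthetic
from calyxpath.traj_io import read_topology

PEPTIDE_PDB = """\
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.009  11.420  10.000  1.00  0.00           C
ATOM      4  O   ALA A   1      11.251  12.390  10.000  1.00  0.00           O
ATOM      5  N   GLY A   2      13.330  11.540  10.000  1.00  0.00           N
ATOM      6  CA  GLY A   2      13.950  12.850  10.000  1.00  0.00           C
ATOM      7  C   SER A   3      15.470  12.770  10.000  1.00  0.00           C
ATOM      8  O   SER A   3      16.090  11.710  10.000  1.00  0.00           O
ATOM      9  CA  VAL A   4      16.150  14.110  10.000  1.00  0.00           C
HETATM   10  C1  BIO A 201      20.000  14.000  10.000  1.00  0.00           C
HETATM   11  O   HOH A 301      25.000  15.000  10.000  1.00  0.00           O
END
"""

# same peptide without the element columns: masses must come from atom names
PEPTIDE_PDB_NO_ELEM = "\n".join(
    line[:54] if line.startswith(("ATOM", "HETATM")) else line
    for line in PEPTIDE_PDB.splitlines()
) + "\n"


@pytest.fixture
def peptide_pdb(tmp_path):
    p = tmp_path / "peptide.pdb"
    p.write_text(PEPTIDE_PDB)
    return p


@pytest.fixture
def peptide_pdb_no_elem(tmp_path):
    p = tmp_path / "peptide_noelem.pdb"
    p.write_text(PEPTIDE_PDB_NO_ELEM)
    return p


@pytest.fixture
def peptide_topology(peptide_pdb):
    return read_topology(peptide_pdb)


@pytest.fixture(scope="session")
def binding_scenario():
    """Default five-step binding scenario with its planted truth."""
    spec = synthetic.BindingScenarioSpec(seed=0)
    traj, states, traces = synthetic.gen_binding_trajectory(spec)
    return spec, traj, states, traces


@pytest.fixture(scope="session")
def small_gaussian_ensemble():
    """Small analytic work ensemble for fast dcTMD unit tests."""
    spec = synthetic.PullSimSpec(n_replicas=64, t_total=1000.0, seed=3)
    ens, truth = synthetic.gen_work_ensemble(spec, mode="gaussian_analytic")
    return spec, ens, truth


def rigid_transform(coords: np.ndarray, angle: float, axis: np.ndarray,
                    shift: np.ndarray) -> np.ndarray:
    """Rotate coordinates about an axis through the origin, then translate."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return coords @ rot.T + np.asarray(shift, dtype=float)
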