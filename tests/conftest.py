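"""Shared fixtures: tiny in-memory PDB texts and synthetic stand-ins.

All fixture data are generated programmatically; the pocket-structure
fixture is a SYNTHETIC stand-in with a geometry chosen to resemble the
published cryo-EM pocket (anchor Cα pair 8.5 Å apart), not real deposited
coordinates.
"""

from __future__ import annotations

import numpy as np
import pytest

from tarp8.mol_io import Atom, Frame, Trajectory


TWO_ATOM_PDB = """\
ATOM      1  CA  VAL E 176       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY E 209      10.000   0.000   0.000  1.00  0.00           C
END
"""

MULTI_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  VAL E 176       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY E 209       8.500   0.000   0.000  1.00  0.00           C
ATOM      3  OD1 ASN E 172       2.000   3.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  CA  VAL E 176       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY E 209       9.400   0.000   0.000  1.00  0.00           C
ATOM      3  OD1 ASN E 172       2.000   3.100   0.000  1.00  0.00           O
ENDMDL
END
"""

# Synthetic stand-in for the real pocket structure (not deposited data):
# chain E carries the two selectivity anchors with an 8.5 Å Cα separation.
SYNTHETIC_POCKET_PDB = """\
ATOM      1  N   VAL E 176      -1.200   0.800   0.300  1.00  0.00           N
ATOM      2  CA  VAL E 176       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CB  VAL E 176       0.400  -1.100   0.900  1.00  0.00           C
ATOM      4  OD1 ASN E 172       2.100   3.200   0.500  1.00  0.00           O
ATOM      5  CA  GLY E 209       8.500   0.000   0.000  1.00  0.00           C
ATOM      6  N   GLY E 209       9.400   1.000  -0.400  1.00  0.00           N
ATOM      7  CA  PHE F 205       5.000   6.000   1.000  1.00  0.00           C
END
"""


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two_atom.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture
def multi_model_pdb(tmp_path):
    p = tmp_path / "multi.pdb"
    p.write_text(MULTI_MODEL_PDB)
    return p


@pytest.fixture
def synthetic_pocket_pdb(tmp_path):
    p = tmp_path / "synthetic_pocket.pdb"
    p.write_text(SYNTHETIC_POCKET_PDB)
    return p


def make_trajectory(coords_per_frame, times=None, atoms=None) -> Trajectory:
    """Build a trajectory from a (n_frames, n_atoms, 3) nm array."""
    coords = np.asarray(coords_per_frame, dtype=float)
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    if atoms is None:
        atoms = [
            Atom(serial=i + 1, name=f"C{i + 1}", element="C", res_name="UNK",
                 res_seq=i + 1, chain_id="A", mass=12.011)
            for i in range(n_atoms)
        ]
    return Trajectory(
        atoms=atoms,
        frames=[Frame(time=float(t), coords=c) for t, c in zip(times, coords)],
    )
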