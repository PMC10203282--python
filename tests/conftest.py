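"""Shared fixtures: handcrafted mmCIF texts and seeded synthetic inputs."""

import numpy as np
import pytest

from metabolon import synthetic
from metabolon.structure_io import parse_structure

# three residues, residue 2 unobserved; flanking Cα 5 Å apart (3-4-5 triangle)
MINIMAL_CIF = """\
data_mini
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 0.000 0.000 0.000 1.00 0.00 1 ALA A 1
ATOM 2 C CA . GLY A 3 3.000 4.000 0.000 1.00 0.00 3 GLY A 1
#
loop_
_pdbx_unobs_or_zero_occ_residues.id
_pdbx_unobs_or_zero_occ_residues.PDB_model_num
_pdbx_unobs_or_zero_occ_residues.polymer_flag
_pdbx_unobs_or_zero_occ_residues.occupancy_flag
_pdbx_unobs_or_zero_occ_residues.auth_asym_id
_pdbx_unobs_or_zero_occ_residues.auth_comp_id
_pdbx_unobs_or_zero_occ_residues.auth_seq_id
1 1 Y 1 A SER 2
#
"""

NO_GAP_CIF = """\
data_nogap
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_comp_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 0.000 0.000 0.000 1.00 0.00 1 ALA A 1
ATOM 2 C CA . GLY A 2 3.800 0.000 0.000 1.00 0.00 2 GLY A 1
ATOM 3 C CA . SER A 3 7.600 0.000 0.000 1.00 0.00 3 SER A 1
#
"""


@pytest.fixture
def minimal_model():
    return parse_structure(MINIMAL_CIF)


@pytest.fixture
def no_gap_model():
    return parse_structure(NO_GAP_CIF)


@pytest.fixture(scope="session")
def seed7_structure():
    """Seed-7 synthetic mmCIF with two excised segments, plus its truth ledger."""
    text, ledger = synthetic.gen_structure(200, 2, seed=7)
    return text, ledger


@pytest.fixture(scope="session")
def walk_model_seed11():
    return synthetic.gen_structure_model(300, seed=11)


def rotation_about_z(angle_deg: float) -> np.ndarray:
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
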