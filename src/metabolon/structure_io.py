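"""Structural model I/O and rigid-body geometry.

Reads mmCIF models (coordinates plus the ``_pdbx_unobs_or_zero_occ_residues``
category that records unmodelled or zero-occupancy residues), extracts maximal
runs of consecutive unobserved residues as :class:`UnobservedRegion` objects,
measures the end-to-end Cα–Cα distance between the observed residues flanking
each run, and provides Kabsch least-squares superposition and inter-chain
rotation-angle computations used for trimer rotational-displacement analysis.

Conventions:

* author residue numbering (``auth_seq_id``) throughout — the unobserved
  category is authored in author numbering;
* only the first model of a multi-model file is surveyed;
* zero-occupancy records are treated identically to unobserved ones (the
  source category mixes both);
* for alternate locations the highest-occupancy altloc wins, ties broken
  alphabetically;
* terminal unobserved runs (one flank absent) are kept as regions but are
  ineligible for distance statistics.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

ABSENT = None  # sentinel for a missing flank at a chain terminus


class StructureParseError(ValueError):
    """Raised when an mmCIF document cannot be interpreted."""


@dataclass(frozen=True)
class AtomSite:
    """One atom record (author numbering, model 1, chosen altloc)."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: tuple[float, float, float]
    model_number: int = 1
    occupancy: float = 1.0
    altloc: str = ""
    element: str = ""


@dataclass(frozen=True)
class UnobservedResidue:
    """One raw record from the unobserved/zero-occupancy category."""

    chain_id: str
    residue_index: int
    residue_name: str
    zero_occupancy: bool = False


@dataclass
class StructureModel:
    """Coordinates plus raw unobserved-residue records for one structure."""

    structure_id: str
    atoms: list[AtomSite]
    unobserved: list[UnobservedResidue] = field(default_factory=list)

    _ca_index: dict | None = field(default=None, repr=False, compare=False)

    # -- indexed access -------------------------------------------------

    def _index(self) -> dict:
        if self._ca_index is None:
            idx: dict[tuple[str, int], dict[str, np.ndarray]] = {}
            for a in self.atoms:
                idx.setdefault((a.chain_id, a.residue_index), {})[a.atom_name] = np.asarray(
                    a.position, dtype=float
                )
            self._ca_index = idx
        return self._ca_index

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def observed_residues(self, chain_id: str) -> list[int]:
        """Sorted author residue numbers with at least one atom in *chain_id*."""
        nums = {a.residue_index for a in self.atoms if a.chain_id == chain_id}
        return sorted(nums)

    def ca_position(self, chain_id: str, residue_index: int) -> np.ndarray | None:
        return self._index().get((chain_id, residue_index), {}).get("CA")

    def ca_trace(self, chain_id: str) -> tuple[list[int], np.ndarray]:
        """Residue numbers and Cα coordinates of one chain, in sequence order."""
        nums = [n for n in self.observed_residues(chain_id) if self.ca_position(chain_id, n) is not None]
        coords = np.array([self.ca_position(chain_id, n) for n in nums], dtype=float)
        return nums, coords.reshape(len(nums), 3)

    def heavy_atoms(self) -> tuple[list[tuple[str, int]], np.ndarray]:
        """All non-hydrogen atoms as (residue labels, n×3 coordinates)."""
        labels: list[tuple[str, int]] = []
        coords: list[tuple[float, float, float]] = []
        for a in self.atoms:
            elem = a.element or a.atom_name[:1]
            if elem.upper().strip() in ("H", "D"):
                continue
            labels.append((a.chain_id, a.residue_index))
            coords.append(a.position)
        return labels, np.asarray(coords, dtype=float).reshape(len(labels), 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with every atom position mapped through x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            AtomSite(
                a.chain_id,
                a.residue_index,
                a.residue_name,
                a.atom_name,
                tuple(R @ np.asarray(a.position) + t),
                a.model_number,
                a.occupancy,
                a.altloc,
                a.element,
            )
            for a in self.atoms
        ]
        return StructureModel(self.structure_id, atoms, list(self.unobserved))


@dataclass(frozen=True)
class UnobservedRegion:
    """A maximal run of consecutive unobserved residues in one chain."""

    structure_id: str
    chain_id: str
    start_index: int
    end_index: int
    sequence: str | None = None
    left_flank: int | None = ABSENT
    right_flank: int | None = ABSENT

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class RegionDistanceRecord:
    """An unobserved region with its flank-to-flank Cα–Cα distance."""

    region: UnobservedRegion
    distance: float | None
    eligible: bool


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform mapping a moving set onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    @property
    def rotation_angle(self) -> float:
        """Rotation magnitude in degrees, from the trace of the rotation matrix."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_UNOBS_PREFIX = "_pdbx_unobs_or_zero_occ_residues."


def parse_structure(mmcif_text: str, structure_id: str | None = None) -> StructureModel:
    """Parse mmCIF text into a :class:`StructureModel`.

    Loads polymer (ATOM) records of the first model, resolving alternate
    locations to the highest-occupancy conformer, and parses the
    ``_pdbx_unobs_or_zero_occ_residues`` category when present (absence is not
    an error and yields an empty list).
    """
    try:
        doc = gemmi.cif.read_string(mmcif_text)
        block = doc.sole_block()
    except (RuntimeError, ValueError) as exc:  # gemmi reports category + line
        raise StructureParseError(f"malformed mmCIF: {exc}") from exc

    if not block.find_loop("_atom_site.id") and not block.find_values("_atom_site.id"):
        raise StructureParseError("mmCIF document has no _atom_site category")

    try:
        st = gemmi.make_structure_from_block(block)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"malformed atom_site loop: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError("no coordinate model in _atom_site")

    model = st[0]
    # highest-occupancy altloc per (chain, residue, atom name); ties alphabetical
    best: dict[tuple[str, int, str], AtomSite] = {}
    order: list[tuple[str, int, str]] = []
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H":  # waters/ligands are outside the survey
                continue
            for atom in residue:
                key = (chain.name, residue.seqid.num, atom.name)
                site = AtomSite(
                    chain_id=chain.name,
                    residue_index=residue.seqid.num,
                    residue_name=residue.name,
                    atom_name=atom.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    model_number=1,
                    occupancy=atom.occ,
                    altloc=atom.altloc or "",
                    element=atom.element.name,
                )
                prev = best.get(key)
                if prev is None:
                    best[key] = site
                    order.append(key)
                elif (site.occupancy, -ord(site.altloc or "~")) > (
                    prev.occupancy,
                    -ord(prev.altloc or "~"),
                ):
                    best[key] = site
    atoms = [best[k] for k in order]
    for a in atoms:
        if not all(math.isfinite(v) for v in a.position):
            raise StructureParseError(
                f"non-finite coordinate for atom {a.atom_name} of "
                f"{a.chain_id}/{a.residue_index} in _atom_site"
            )

    unobserved: list[UnobservedResidue] = []
    table = block.find(
        _UNOBS_PREFIX,
        ["auth_asym_id", "auth_seq_id", "?auth_comp_id", "?occupancy_flag", "?PDB_model_num"],
    )
    for row in table:
        model_num = row[4] if table.has_column(4) else "1"
        if model_num not in ("1", ".", "?", ""):
            continue
        try:
            seq = int(row[1])
        except ValueError as exc:
            raise StructureParseError(
                f"unparseable auth_seq_id {row[1]!r} in {_UNOBS_PREFIX.rstrip('.')}"
            ) from exc
        comp = row[2] if table.has_column(2) else "UNK"
        occ_flag = row[3] if table.has_column(3) else "1"
        unobserved.append(
            UnobservedResidue(
                chain_id=row[0],
                residue_index=seq,
                residue_name=comp if comp not in (".", "?") else "UNK",
                zero_occupancy=(occ_flag == "0"),
            )
        )

    sid = structure_id or block.name or "structure"
    return StructureModel(sid, atoms, unobserved)


def read_structure(path) -> StructureModel:
    """Read an mmCIF file from *path*."""
    with open(path) as fh:
        return parse_structure(fh.read())


# ---------------------------------------------------------------------------
# Writing (minimal, fixture-oriented)
# ---------------------------------------------------------------------------


def write_mmcif(model: StructureModel) -> str:
    """Serialize a model to minimal mmCIF text (atom_site + unobserved loop)."""
    out = io.StringIO()
    out.write(f"data_{model.structure_id}\n")
    out.write("#\nloop_\n")
    for tag in (
        "group_PDB",
        "id",
        "type_symbol",
        "label_atom_id",
        "label_alt_id",
        "label_comp_id",
        "label_asym_id",
        "label_seq_id",
        "Cartn_x",
        "Cartn_y",
        "Cartn_z",
        "occupancy",
        "B_iso_or_equiv",
        "auth_seq_id",
        "auth_comp_id",
        "auth_asym_id",
        "pdbx_PDB_model_num",
    ):
        out.write(f"_atom_site.{tag}\n")
    for i, a in enumerate(model.atoms, start=1):
        x, y, z = a.position
        elem = a.element or a.atom_name[:1]
        out.write(
            f"ATOM {i} {elem} {a.atom_name} {a.altloc or '.'} {a.residue_name} "
            f"{a.chain_id} {a.residue_index} {x:.4f} {y:.4f} {z:.4f} "
            f"{a.occupancy:.2f} 0.00 {a.residue_index} {a.residue_name} {a.chain_id} 1\n"
        )
    if model.unobserved:
        out.write("#\nloop_\n")
        for tag in (
            "id",
            "PDB_model_num",
            "polymer_flag",
            "occupancy_flag",
            "auth_asym_id",
            "auth_comp_id",
            "auth_seq_id",
        ):
            out.write(f"_pdbx_unobs_or_zero_occ_residues.{tag}\n")
        for i, u in enumerate(model.unobserved, start=1):
            out.write(
                f"{i} 1 Y {'0' if u.zero_occupancy else '1'} "
                f"{u.chain_id} {u.residue_name} {u.residue_index}\n"
            )
    out.write("#\n")
    return out.getvalue()


def write_minimal_pdb(model: StructureModel) -> str:
    """Serialize to a minimal PDB text (ATOM records only)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        x, y, z = a.position
        elem = (a.element or a.atom_name[:1]).rjust(2)
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{a.altloc or ' '}{a.residue_name:<3s} "
            f"{a.chain_id[:1]}{a.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          {elem}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Unobserved regions and flank distances
# ---------------------------------------------------------------------------


def extract_missing_regions(model: StructureModel) -> list[UnobservedRegion]:
    """Merge consecutive unobserved residues into maximal per-chain regions.

    Flanks are the nearest observed residues on either side; a run at a chain
    terminus keeps ``None`` on the open side and is thereby ineligible for
    distance statistics downstream.
    """
    regions: list[UnobservedRegion] = []
    by_chain: dict[str, list[UnobservedResidue]] = {}
    for u in model.unobserved:
        by_chain.setdefault(u.chain_id, []).append(u)

    for chain_id, recs in by_chain.items():
        recs = sorted({r.residue_index: r for r in recs}.values(), key=lambda r: r.residue_index)
        observed = model.observed_residues(chain_id)
        runs: list[list[UnobservedResidue]] = []
        for r in recs:
            if runs and r.residue_index == runs[-1][-1].residue_index + 1:
                runs[-1].append(r)
            else:
                runs.append([r])
        for run in runs:
            start, end = run[0].residue_index, run[-1].residue_index
            left = max((n for n in observed if n < start), default=ABSENT)
            right = min((n for n in observed if n > end), default=ABSENT)
            seq = "".join(gemmi.find_tabulated_residue(r.residue_name).one_letter_code.upper()
                          if gemmi.find_tabulated_residue(r.residue_name) else "X"
                          for r in run)
            regions.append(
                UnobservedRegion(
                    structure_id=model.structure_id,
                    chain_id=chain_id,
                    start_index=start,
                    end_index=end,
                    sequence=seq,
                    left_flank=left,
                    right_flank=right,
                )
            )
    regions.sort(key=lambda r: (r.chain_id, r.start_index))
    return regions


def flank_distance(model: StructureModel, region: UnobservedRegion) -> RegionDistanceRecord:
    """End-to-end Cα–Cα distance between the residues flanking a region.

    The distance is undefined (record ineligible) when a flank is absent —
    the run touches a chain terminus — or when a flanking residue carries no
    Cα atom.
    """
    if region.left_flank is ABSENT or region.right_flank is ABSENT:
        return RegionDistanceRecord(region, None, False)
    ca_l = model.ca_position(region.chain_id, region.left_flank)
    ca_r = model.ca_position(region.chain_id, region.right_flank)
    if ca_l is None or ca_r is None:
        return RegionDistanceRecord(region, None, False)
    return RegionDistanceRecord(region, float(np.linalg.norm(ca_l - ca_r)), True)


def survey_structure(model: StructureModel) -> list[RegionDistanceRecord]:
    """All regions of a model with their flank distances."""
    return [flank_distance(model, r) for r in extract_missing_regions(model)]


def region_table(records: Iterable[RegionDistanceRecord]) -> pd.DataFrame:
    """Flat region/distance table (TSV-exportable)."""
    rows = [
        {
            "structure_id": r.region.structure_id,
            "chain": r.region.chain_id,
            "start": r.region.start_index,
            "end": r.region.end_index,
            "length": r.region.length,
            "distance": r.distance if r.distance is not None else float("nan"),
            "eligible": r.eligible,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["structure_id", "chain", "start", "end", "length", "distance", "eligible"])


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------


def superpose(coords_ref: Sequence, coords_mov: Sequence) -> Superposition:
    """Kabsch least-squares superposition of *coords_mov* onto *coords_ref*.

    Returns the proper rotation ``R`` (det +1) and translation ``t`` minimising
    ``sum ||R m_i + t - r_i||^2``, with the attained RMSD.
    """
    P = np.asarray(coords_ref, dtype=float)
    Q = np.asarray(coords_mov, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-length lists of 3-vectors")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (collinear or rank-deficient) coordinate set")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    diff = Q @ R.T + t - P
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def _matched_ca(model_x: StructureModel, model_y: StructureModel, chain: str) -> tuple[np.ndarray, np.ndarray]:
    nx, cx = model_x.ca_trace(chain)
    ny, cy = model_y.ca_trace(chain)
    sx, sy = set(nx), set(ny)
    if sx != sy:
        unpaired = sorted(sx.symmetric_difference(sy))
        raise ValueError(f"unmatched residue correspondence in chain {chain}: unpaired residues {unpaired}")
    common = sorted(sx)
    ix = {n: i for i, n in enumerate(nx)}
    iy = {n: i for i, n in enumerate(ny)}
    return cx[[ix[n] for n in common]], cy[[iy[n] for n in common]]


def _intra_angle(model: StructureModel, align_chain: str, target_chain: str) -> float:
    na, ca = model.ca_trace(align_chain)
    nt, ct = model.ca_trace(target_chain)
    sa, st_ = set(na), set(nt)
    if sa != st_:
        unpaired = sorted(sa.symmetric_difference(st_))
        raise ValueError(
            f"unmatched residue correspondence between chains {align_chain} and {target_chain}: "
            f"unpaired residues {unpaired}"
        )
    common = sorted(sa)
    ia = {n: i for i, n in enumerate(na)}
    it = {n: i for i, n in enumerate(nt)}
    sup = superpose(ct[[it[n] for n in common]], ca[[ia[n] for n in common]])
    return sup.rotation_angle


def chain_rotation_displacement(
    trimer_a: StructureModel,
    trimer_b: StructureModel,
    align_chain: str,
    target_chain: str,
) -> float:
    """Signed rotational displacement of *target_chain* between two trimers.

    Both structures are first brought into the frame of *align_chain* (which
    leaves the intra-structure align→target rotation angles unchanged); the
    returned value is the angle in *trimer_b* minus the angle in *trimer_a*,
    in degrees, so that ``displacement(a, b) == -displacement(b, a)``.
    """
    ca_ref, cb_mov = _matched_ca(trimer_a, trimer_b, align_chain)
    sup = superpose(ca_ref, cb_mov)
    trimer_b_aligned = trimer_b.transformed(sup.rotation, sup.translation)
    angle_a = _intra_angle(trimer_a, align_chain, target_chain)
    angle_b = _intra_angle(trimer_b_aligned, align_chain, target_chain)
    return angle_b - angle_a
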