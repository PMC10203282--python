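"""Docking-ensemble contact frequencies and "guiding surface" hotspots.

Given a receptor and an ensemble of docked ligand poses, a receptor residue is
in contact with a pose when any of its heavy atoms lies within a cutoff
(default 5 Å) of any ligand heavy atom.  Contact counts accumulated over the
ensemble, normalised by the number of poses, give per-residue contact
frequencies; the high-frequency residues form the guiding surface that steers
the lipoyl domain toward its binding pocket.

The "top quartile (above 25%)" hotspot phrase admits two readings, both
implemented:

* ``rule="percentile"`` (default) — residues whose frequency is at or above
  the 75th percentile of the nonzero frequencies (ties at the percentile are
  included, so a flat table returns every contacting residue);
* ``rule="absolute"`` — residues contacting in strictly more than 25% of
  poses.

The neighbour search uses a k-d tree but is exact, i.e. identical to the
all-pairs distance scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import StructureModel

DEFAULT_CUTOFF = 5.0  # Å, heavy-atom proximity rule

ResidueId = tuple[str, int]  # (chain, author residue number)


@dataclass(frozen=True)
class PoseEnsemble:
    """A receptor with an ensemble of docked ligand poses."""

    receptor: StructureModel
    poses: tuple[StructureModel, ...]

    def __post_init__(self):
        if len(self.poses) < 1:
            raise ValueError("a pose ensemble needs at least one pose")

    @property
    def n_poses(self) -> int:
        return len(self.poses)


@dataclass
class ContactFrequencyTable:
    """Per-residue contact counts and frequencies over an ensemble."""

    residues: tuple[ResidueId, ...]
    counts: np.ndarray
    n_poses: int

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_poses

    def to_frame(self) -> pd.DataFrame:
        hot = hotspots(self)
        return pd.DataFrame(
            {
                "chain": [r[0] for r in self.residues],
                "residue": [r[1] for r in self.residues],
                "contact_count": self.counts,
                "frequency": self.frequencies,
                "hotspot": [r in hot for r in self.residues],
            }
        )


def contact_residues(receptor: StructureModel, pose: StructureModel, cutoff: float = DEFAULT_CUTOFF) -> set[ResidueId]:
    """Receptor residues with any heavy atom within *cutoff* of any pose heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec_labels, rec_xyz = receptor.heavy_atoms()
    pose_labels, pose_xyz = pose.heavy_atoms()
    if len(pose_labels) == 0:
        raise ValueError("pose has no heavy atoms")
    if len(rec_labels) == 0:
        return set()
    tree = cKDTree(pose_xyz)
    # exact radius query: identical to the brute-force all-pairs scan
    hits = tree.query_ball_point(rec_xyz, r=cutoff)
    return {rec_labels[i] for i, h in enumerate(hits) if h}


def frequency_table(ensemble: PoseEnsemble, cutoff: float = DEFAULT_CUTOFF) -> ContactFrequencyTable:
    """Contact counts accumulated over all poses, normalised by pose count."""
    residues: list[ResidueId] = []
    seen: dict[ResidueId, int] = {}
    for a in ensemble.receptor.atoms:
        rid = (a.chain_id, a.residue_index)
        if rid not in seen:
            seen[rid] = len(residues)
            residues.append(rid)
    counts = np.zeros(len(residues), dtype=int)
    for pose in ensemble.poses:
        for rid in contact_residues(ensemble.receptor, pose, cutoff):
            counts[seen[rid]] += 1
    return ContactFrequencyTable(residues=tuple(residues), counts=counts, n_poses=ensemble.n_poses)


def hotspots(table: ContactFrequencyTable, rule: str = "percentile", absolute_fraction: float = 0.25) -> set[ResidueId]:
    """Guiding-surface residues under the chosen top-quartile reading."""
    freqs = table.frequencies
    nonzero = freqs[freqs > 0]
    if nonzero.size == 0:
        return set()
    if rule == "percentile":
        thr = float(np.percentile(nonzero, 75))
        mask = freqs >= thr
    elif rule == "absolute":
        mask = freqs > absolute_fraction
    else:
        raise ValueError(f"unknown hotspot rule {rule!r}; use 'percentile' or 'absolute'")
    return {r for r, m in zip(table.residues, mask) if m}


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index of two residue sets (1.0 for two empty sets)."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
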