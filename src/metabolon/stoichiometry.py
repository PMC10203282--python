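"""iBAQ-anchored stoichiometry of a multi-enzyme complex.

iBAQ scores (summed peptide intensities normalised by theoretically
observable peptides) are proportional to protein copy number within one
sample, so anchoring one subunit to a known copy count — the 24-mer E2o core
of the metabolon — converts relative abundances to per-complex copy numbers.
Copies are reported unrounded; the resulting stoichiometry is qualitative
(statements of the "<10 dimers", "~4 copies" kind), and assembly units
divide copies by the oligomeric state (1 for monomers, 2 for dimers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

_OLIGOMER_SIZE = {"monomer": 1, "dimer": 2}


@dataclass(frozen=True)
class AbundanceTable:
    """Per-protein iBAQ scores with oligomeric states."""

    ibaq: dict[str, float]
    oligomeric_state: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for p, v in self.ibaq.items():
            if v < 0:
                raise ValueError(f"negative iBAQ for {p}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        cols = {c.lower(): c for c in df.columns}
        ibaq = dict(zip(df[cols["protein"]].astype(str), df[cols["ibaq"]].astype(float)))
        olig = {}
        if "oligomer" in cols:
            olig = dict(zip(df[cols["protein"]].astype(str), df[cols["oligomer"]].astype(str)))
        return cls(ibaq=ibaq, oligomeric_state=olig)

    def oligomer_size(self, protein: str) -> int:
        return _OLIGOMER_SIZE.get(self.oligomeric_state.get(protein, "monomer"), 1)


@dataclass(frozen=True)
class StoichiometryEstimate:
    """Copy numbers per complex, anchored to one subunit."""

    copies: dict[str, float]
    assembly_units: dict[str, float]
    anchor: tuple[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": list(self.copies),
                "copies": list(self.copies.values()),
                "assembly_units": [self.assembly_units[p] for p in self.copies],
            }
        )


def relative_copies(table: AbundanceTable, anchor: tuple[str, float] = ("E2o", 24.0)) -> StoichiometryEstimate:
    """Copy numbers from iBAQ ratios, anchored to a fixed-copy subunit.

    ``copies_i = anchor_copies × iBAQ_i / iBAQ_anchor``; the transform is
    invariant to global rescaling of the iBAQ column and returns the anchor's
    copy count exactly.
    """
    protein, n_anchor = anchor
    if protein not in table.ibaq:
        raise ValueError(f"anchor protein {protein!r} absent from the abundance table")
    ref = table.ibaq[protein]
    if ref <= 0:
        raise ValueError(f"anchor protein {protein!r} has non-positive iBAQ")
    copies = {p: n_anchor * v / ref for p, v in table.ibaq.items()}
    units = {p: c / table.oligomer_size(p) for p, c in copies.items()}
    return StoichiometryEstimate(copies=copies, assembly_units=units, anchor=(protein, float(n_anchor)))


def max_occupancy_chains(
    core_monomers: int,
    tether_monomers: int,
    dimers_per_class: Sequence[int],
) -> int:
    """Total polypeptide chains at maximal peripheral occupancy.

    core monomers + tether monomers + two chains per tethered dimer, summed
    over dimer classes; e.g. a 24-mer core with 24 tethers each able to hold
    one of 12 + 12 dimers totals 96 chains.
    """
    if core_monomers < 0 or tether_monomers < 0 or any(d < 0 for d in dimers_per_class):
        raise ValueError("counts must be non-negative")
    return int(core_monomers) + int(tether_monomers) + sum(2 * int(d) for d in dimers_per_class)


def qualitative_band(copies: float) -> str:
    """Render a copy number the way qualitative stoichiometries are phrased."""
    import math

    if abs(copies - round(copies)) < 0.05:
        return f"{round(copies)}"
    return f"<{math.ceil(copies)} (~{copies:.1f})"
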