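"""Crosslink ledgers: parsing, structure mapping, satisfaction, distributions.

A crosslink ledger is a delimited table of residue-pair crosslinks (protein A,
residue A, protein B, residue B, replicate).  Records are deduplicated on the
unordered (protein, residue) pair; mapping onto a structural model takes the
minimum Cα–Cα distance over all allowed chain assignments (the standard
resolution of homodimer ambiguity), and a link is *satisfied* when its mapped
distance is at or below the crosslinker-compatible cutoff.  The default cutoff
is 30 Å Cα–Cα, the community convention for BS3 (11.4 Å spacer plus two lysine
side chains and backbone tolerance); the experimental satisfaction percentages
this pipeline emulates were reported without a stated cutoff, so reports
should quote fractions at 25/30/35 Å.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import StructureModel

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 30.0  # Å Cα–Cα, BS3 convention
REPORT_THRESHOLDS = (25.0, 30.0, 35.0)

UNMAPPED = None

_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "protein_a": ("proteina", "protein_a", "protein1", "protein 1"),
    "res_a": ("resa", "res_a", "residuea", "residue_a", "abspos1"),
    "protein_b": ("proteinb", "protein_b", "protein2", "protein 2"),
    "res_b": ("resb", "res_b", "residueb", "residue_b", "abspos2"),
    "replicate": ("replicate", "rep", "run"),
    "score": ("score", "match score"),
}


@dataclass(frozen=True)
class CrosslinkRecord:
    """One unique residue-pair crosslink."""

    protein_a: str
    res_a: int
    protein_b: str
    res_b: int
    replicates: tuple[str, ...] = ()
    score: float | None = None

    @property
    def link_type(self) -> str:
        return "intra" if self.protein_a == self.protein_b else "inter"

    @property
    def key(self) -> frozenset:
        return frozenset({(self.protein_a, self.res_a), (self.protein_b, self.res_b)})


@dataclass
class MappedLink:
    """A crosslink with its model distance and chain assignment."""

    record: CrosslinkRecord
    distance: float | None
    chain_assignment: tuple[str, str] | None
    satisfied: bool | None = None


@dataclass(frozen=True)
class DistanceDistribution:
    """Log-normal MLE fit of mapped crosslink distances."""

    distances: tuple[float, ...]
    lognormal_mu: float
    lognormal_sigma: float
    gof_stat: float  # Kolmogorov–Smirnov statistic vs the fitted log-normal


@dataclass(frozen=True)
class SatisfactionResult:
    fraction: float
    n_satisfied: int
    n_mapped: int
    n_unmapped: int
    threshold: float


@dataclass(frozen=True)
class LinkSummary:
    intra_per_protein: dict[str, int]
    inter_per_pair: dict[tuple[str, str], int]

    @property
    def n_intra(self) -> int:
        return sum(self.intra_per_protein.values())

    @property
    def n_inter(self) -> int:
        return sum(self.inter_per_pair.values())

    @property
    def n_total(self) -> int:
        return self.n_intra + self.n_inter

    def inter_per_protein(self) -> dict[str, int]:
        """Inter-link counts attributed to each protein (each link counts for both partners)."""
        out: dict[str, int] = {}
        for (a, b), n in self.inter_per_pair.items():
            out[a] = out.get(a, 0) + n
            out[b] = out.get(b, 0) + n
        return out


# ---------------------------------------------------------------------------
# Ledger I/O
# ---------------------------------------------------------------------------


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [c for c in ("protein_a", "res_a", "protein_b", "res_b", "replicate") if c not in resolved]
    if missing:
        raise ValueError(f"ledger is missing required column(s): {missing}")
    return resolved


def load_ledger(source) -> list[CrosslinkRecord]:
    """Read a crosslink ledger (path, file-like, text, or DataFrame).

    Rows are deduplicated on the unordered (protein, residue) pair; replicate
    provenance is merged.  Self-pairs (identical residue on the same protein)
    and rows with unparseable residue indices are skipped, with the skip count
    logged.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        if isinstance(source, str) and ("\n" in source or "\t" in source or "," in source):
            source = io.StringIO(source)
        df = pd.read_csv(source, sep=None, engine="python")
    cols = _resolve_columns(df.columns)

    merged: dict[frozenset, CrosslinkRecord] = {}
    n_skipped = 0
    for _, row in df.iterrows():
        try:
            pa, pb = str(row[cols["protein_a"]]), str(row[cols["protein_b"]])
            ra, rb = int(row[cols["res_a"]]), int(row[cols["res_b"]])
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        if ra < 1 or rb < 1 or (pa == pb and ra == rb):
            n_skipped += 1
            continue
        rep = str(row[cols["replicate"]])
        score = float(row[cols["score"]]) if "score" in cols and pd.notna(row[cols["score"]]) else None
        # canonical orientation for the stored record
        if (pa, ra) > (pb, rb):
            pa, ra, pb, rb = pb, rb, pa, ra
        rec = CrosslinkRecord(pa, ra, pb, rb, replicates=(rep,), score=score)
        prev = merged.get(rec.key)
        if prev is None:
            merged[rec.key] = rec
        else:
            reps = tuple(dict.fromkeys(prev.replicates + (rep,)))
            merged[rec.key] = replace(prev, replicates=reps)
    if n_skipped:
        logger.warning("load_ledger: skipped %d unusable row(s)", n_skipped)
    return list(merged.values())


def ledger_frame(records: Iterable[CrosslinkRecord]) -> pd.DataFrame:
    rows = [
        {
            "ProteinA": r.protein_a,
            "ResA": r.res_a,
            "ProteinB": r.protein_b,
            "ResB": r.res_b,
            "Replicate": ";".join(r.replicates),
            "LinkType": r.link_type,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["ProteinA", "ResA", "ProteinB", "ResB", "Replicate", "LinkType"])


# ---------------------------------------------------------------------------
# Mapping and statistics
# ---------------------------------------------------------------------------


def map_links(
    model: StructureModel,
    records: Iterable[CrosslinkRecord],
    chain_map: Mapping[str, Iterable[str]],
) -> list[MappedLink]:
    """Map crosslinks onto a model as minimum Cα–Cα distances.

    *chain_map* assigns each protein identifier the set of chains it may
    occupy (more than one for homo-oligomers); the mapped distance is the
    minimum over all chain-pair assignments.  A link is UNMAPPED (distance
    ``None``) when its protein is absent from the map or a residue lacks a Cα
    in every candidate chain.
    """
    cmap = {p: tuple(cs) for p, cs in chain_map.items()}
    out: list[MappedLink] = []
    for rec in records:
        chains_a = cmap.get(rec.protein_a, ())
        chains_b = cmap.get(rec.protein_b, ())
        best: float | None = None
        best_pair: tuple[str, str] | None = None
        for ca_chain in chains_a:
            pa = model.ca_position(ca_chain, rec.res_a)
            if pa is None:
                continue
            for cb_chain in chains_b:
                pb = model.ca_position(cb_chain, rec.res_b)
                if pb is None:
                    continue
                d = float(np.linalg.norm(pa - pb))
                if best is None or d < best:
                    best, best_pair = d, (ca_chain, cb_chain)
        out.append(MappedLink(record=rec, distance=best, chain_assignment=best_pair))
    return out


def satisfaction(mapped: Sequence[MappedLink], threshold: float = DEFAULT_THRESHOLD) -> SatisfactionResult:
    """Fraction of mapped links with distance at or below *threshold* (inclusive).

    UNMAPPED links are excluded from the denominator; zero mapped links is an
    error rather than a NaN.  Each link's ``satisfied`` flag is set in place.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_mapped = n_sat = n_unmapped = 0
    for link in mapped:
        if link.distance is UNMAPPED:
            link.satisfied = None
            n_unmapped += 1
            continue
        n_mapped += 1
        link.satisfied = link.distance <= threshold
        n_sat += int(link.satisfied)
    if n_mapped == 0:
        raise ValueError("no mapped links: satisfaction is undefined")
    return SatisfactionResult(
        fraction=n_sat / n_mapped,
        n_satisfied=n_sat,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        threshold=threshold,
    )


def satisfaction_profile(mapped: Sequence[MappedLink], thresholds: Sequence[float] = REPORT_THRESHOLDS) -> dict[float, float]:
    """Satisfaction fraction at several cutoffs (cutoff-sensitivity report)."""
    return {t: satisfaction(mapped, t).fraction for t in thresholds}


def fit_distance_distribution(mapped: Sequence[MappedLink] | Sequence[float]) -> DistanceDistribution:
    """Maximum-likelihood log-normal fit of mapped distances, with a KS statistic.

    Parameters are the mean and standard deviation of log distances (the MLE
    for a log-normal); the goodness-of-fit statistic is the one-sample
    Kolmogorov–Smirnov distance against the fitted distribution.
    """
    if mapped and isinstance(mapped[0], MappedLink):
        d = [m.distance for m in mapped if m.distance is not UNMAPPED]
    else:
        d = list(mapped)
    d = np.asarray(d, dtype=float)
    if d.size < 5:
        raise ValueError("log-normal fit requires at least 5 mapped distances")
    if np.any(d <= 0):
        raise ValueError("all distances must be positive for a log-normal fit")
    logd = np.log(d)
    mu = float(logd.mean())
    sigma = float(logd.std(ddof=0))
    if sigma <= 0:
        raise ValueError("degenerate (constant) distances: sigma is zero")
    ks = stats.kstest(d, stats.lognorm(s=sigma, scale=math.exp(mu)).cdf)
    return DistanceDistribution(
        distances=tuple(float(x) for x in d),
        lognormal_mu=mu,
        lognormal_sigma=sigma,
        gof_stat=float(ks.statistic),
    )


def link_summary(records: Iterable[CrosslinkRecord], protein_set: Iterable[str] | None = None) -> LinkSummary:
    """Unique intra-link counts per protein and inter-link counts per pair.

    With *protein_set* given, only links whose proteins all fall inside the
    set are counted; totals satisfy intra + inter = number of unique records
    within the restriction.
    """
    allowed = set(protein_set) if protein_set else None  # empty set -> global totals
    intra: dict[str, int] = {}
    inter: dict[tuple[str, str], int] = {}
    for rec in records:
        if allowed is not None and (rec.protein_a not in allowed or rec.protein_b not in allowed):
            continue
        if rec.link_type == "intra":
            intra[rec.protein_a] = intra.get(rec.protein_a, 0) + 1
        else:
            pair = tuple(sorted((rec.protein_a, rec.protein_b)))
            inter[pair] = inter.get(pair, 0) + 1
    return LinkSummary(intra_per_protein=intra, inter_per_pair=inter)
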