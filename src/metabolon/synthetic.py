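"""Seeded generators for every input the pipeline consumes.

Each generator emulates one class of study input — structures with excised
segments, crosslink ledgers, docking-pose ensembles, absorbance time courses,
abundance tables — and returns, alongside the artifact, a
:class:`GeneratorLedger` holding the ground truth the pipeline should
recover.  All generators are deterministic functions of their parameters and
seed (byte-identical reruns), so round-trip tests can compare pipeline output
to planted truth exactly.

The Cα random walks are not self-avoiding; excluded volume is irrelevant to
the end-to-end distance and contact statistics exercised here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .interface_freq import PoseEnsemble
from .kinetics import AssayConstants, KineticsTrace, substrate_inhibition_rate
from .linker_survey import BinScheme, build_bins, saturation_model
from .structure_io import AtomSite, StructureModel, UnobservedResidue, write_mmcif

CA_STEP = 3.8  # Å, trans Cα–Cα virtual bond length


@dataclass
class GeneratorLedger:
    """Ground truth recorded at generation time."""

    seed: int
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]


def _random_walk(rng: np.random.Generator, n: int, step: float = CA_STEP) -> np.ndarray:
    """An n-point chain with fixed step length and uniform random directions."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(steps * step, axis=0)])
    return coords


# ---------------------------------------------------------------------------
# Structures with excised segments
# ---------------------------------------------------------------------------


def gen_structure(
    n_residues: int,
    n_gaps: int,
    seed: int,
    chain_id: str = "A",
    structure_id: str | None = None,
    max_gap_length: int = 15,
) -> tuple[str, GeneratorLedger]:
    """An mmCIF Cα trace with internal segments moved to the unobserved category.

    The full chain is a 3.8 Å-step random walk; *n_gaps* internal segments are
    excised (listed under ``_pdbx_unobs_or_zero_occ_residues``) such that at
    least one observed residue separates and flanks every gap.  The ledger
    records each region's boundaries and the true flank-to-flank Cα distance.
    """
    rng = np.random.default_rng(seed)
    sid = structure_id or f"synth{seed}"
    if n_gaps < 0 or (n_gaps > 0 and n_residues < 2 * n_gaps + 1):
        raise ValueError("infeasible gap layout: too few residues for the requested gaps")

    if n_gaps:
        cap = max(1, (n_residues - (n_gaps + 1)) // n_gaps)
        gap_lengths = rng.integers(1, min(max_gap_length, cap) + 1, size=n_gaps).tolist()
    else:
        gap_lengths = []
    total_gap = int(sum(gap_lengths))
    n_observed = n_residues - total_gap
    if n_observed < n_gaps + 1:
        raise ValueError("infeasible gap layout: gaps leave too few observed residues")

    # observed spacers around the gaps: each at least 1 residue
    extra = n_observed - (n_gaps + 1)
    spacers = np.ones(n_gaps + 1, dtype=int)
    if extra > 0:
        spacers += rng.multinomial(extra, np.ones(n_gaps + 1) / (n_gaps + 1))

    # round here so the ledger's distances refer to exactly the coordinates written
    coords = np.round(_random_walk(rng, n_residues), 4)
    observed_mask = np.ones(n_residues, dtype=bool)
    regions = []
    pos = 0
    for i, gl in enumerate(gap_lengths):
        pos += int(spacers[i])
        start, end = pos + 1, pos + gl  # author numbering is 1-based
        observed_mask[start - 1 : end] = False
        left, right = start - 1, end + 1
        dist = float(np.linalg.norm(coords[left - 1] - coords[right - 1]))
        regions.append(
            {"chain": chain_id, "start": start, "end": end, "length": gl,
             "left_flank": left, "right_flank": right, "distance": dist}
        )
        pos += gl
    # trailing spacer consumes the rest

    atoms = [
        AtomSite(chain_id, i + 1, "ALA", "CA", tuple(coords[i]), element="C")
        for i in range(n_residues)
        if observed_mask[i]
    ]
    unobserved = [
        UnobservedResidue(chain_id, i + 1, "ALA")
        for i in range(n_residues)
        if not observed_mask[i]
    ]
    model = StructureModel(sid, atoms, unobserved)
    ledger = GeneratorLedger(seed=seed, data={
        "structure_id": sid,
        "chain_id": chain_id,
        "n_residues": n_residues,
        "regions": regions,
        "coords": coords,
        "observed_mask": observed_mask,
    })
    return write_mmcif(model), ledger


def gen_structure_model(n_residues: int, seed: int, chain_id: str = "A",
                        structure_id: str | None = None) -> StructureModel:
    """A fully observed Cα random-walk model (no unobserved loop)."""
    rng = np.random.default_rng(seed)
    coords = _random_walk(rng, n_residues)
    atoms = [
        AtomSite(chain_id, i + 1, "ALA", "CA", tuple(np.round(coords[i], 4)), element="C")
        for i in range(n_residues)
    ]
    return StructureModel(structure_id or f"walk{seed}", atoms)


def gen_globular_receptor(n_residues: int, seed: int, chain_id: str = "R",
                          spacing: float = 6.0,
                          structure_id: str | None = None) -> StructureModel:
    """A coarse globular surface: Cα pseudo-residues on a quasi-uniform sphere.

    Residues sit on a Fibonacci lattice over a sphere whose radius is chosen
    so neighbouring residues are ~*spacing* Å apart (with small radial
    texture), emulating the solvent-exposed surface a docking ligand probes.
    Unlike a random walk, the surface has no fold-backs, so a contact patch
    is spatially separable from the rest of the receptor.
    """
    rng = np.random.default_rng(seed)
    radius = spacing * math.sqrt(n_residues / (4.0 * math.pi))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    atoms = []
    for i in range(n_residues):
        z = 1.0 - 2.0 * (i + 0.5) / n_residues
        r_xy = math.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * i
        unit = np.array([r_xy * math.cos(theta), r_xy * math.sin(theta), z])
        pos = unit * (radius + rng.normal(0.0, 0.3))
        atoms.append(AtomSite(chain_id, i + 1, "ALA", "CA",
                              tuple(np.round(pos, 4)), element="C"))
    return StructureModel(structure_id or f"globe{seed}", atoms)


# ---------------------------------------------------------------------------
# Binned survey points
# ---------------------------------------------------------------------------


def gen_survey_points(
    A: float,
    b: float,
    lengths: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    offset: float = 3.5,
    max_length: int = 250,
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Per-bin mean distances drawn from the saturation model plus Gaussian noise.

    Without explicit *lengths*, the abscissae are the midpoints of the survey
    bin scheme truncated at *max_length*.
    """
    rng = np.random.default_rng(seed)
    if lengths is None:
        scheme = scheme or build_bins(max_length)
        bounds = [scheme.bounds(i) for i in range(scheme.n_bins)]
    else:
        bounds = [(int(L), int(L)) for L in lengths]
    x = np.array([(lo + hi) / 2.0 for lo, hi in bounds])
    y = saturation_model(x, A, b, offset) + rng.normal(0.0, noise_sd, size=x.size)
    return pd.DataFrame(
        {
            "bin_left": [lo for lo, _ in bounds],
            "bin_right": [hi for _, hi in bounds],
            "n": 1,
            "mean_distance": y,
        }
    )


# ---------------------------------------------------------------------------
# Crosslink ledgers
# ---------------------------------------------------------------------------


def gen_crosslinks(
    model: StructureModel,
    n_links: int,
    frac_satisfied: float = 1.0,
    threshold: float = 30.0,
    decoy_rate: float = 0.0,
    seed: int = 0,
    protein: str = "P1",
    replicate: str = "r1",
) -> tuple[pd.DataFrame, GeneratorLedger]:
    """A ledger of intra-protein residue pairs with a planted satisfied fraction.

    Exactly ``round(n_links * frac_satisfied)`` pairs have Cα–Cα distance at
    or below *threshold* in *model*; decoy rows reference residues absent from
    the model (they exercise the UNMAPPED path).  The ledger records each
    pair's true distance and satisfied flag, and the chain map to use.
    """
    rng = np.random.default_rng(seed)
    chain = model.chains()[0]
    nums, coords = model.ca_trace(chain)
    if len(nums) < 3:
        raise ValueError("model too small to draw crosslinks from")
    dmat = squareform(pdist(coords))
    iu = np.triu_indices(len(nums), k=1)
    dists = dmat[iu]
    sat_pool = np.flatnonzero(dists <= threshold)
    unsat_pool = np.flatnonzero(dists > threshold)
    n_sat = int(round(n_links * frac_satisfied))
    n_unsat = n_links - n_sat
    if n_sat > sat_pool.size or n_unsat > unsat_pool.size:
        raise ValueError(
            f"model offers {sat_pool.size} satisfiable and {unsat_pool.size} "
            f"unsatisfiable pairs; cannot plant {n_sat}/{n_unsat}"
        )
    chosen = np.concatenate([
        rng.choice(sat_pool, size=n_sat, replace=False),
        rng.choice(unsat_pool, size=n_unsat, replace=False),
    ])
    rng.shuffle(chosen)

    rows, truth = [], []
    for idx in chosen:
        i, j = int(iu[0][idx]), int(iu[1][idx])
        ra, rb = nums[i], nums[j]
        d = float(dmat[i, j])
        rows.append({"ProteinA": protein, "ResA": ra, "ProteinB": protein,
                     "ResB": rb, "Replicate": replicate})
        truth.append({"res_a": ra, "res_b": rb, "distance": d,
                      "satisfied": d <= threshold})

    n_decoys = int(round(n_links * decoy_rate))
    max_res = max(nums)
    for k in range(n_decoys):
        rows.append({"ProteinA": protein, "ResA": max_res + 100 + k,
                     "ProteinB": protein, "ResB": int(rng.choice(nums)),
                     "Replicate": replicate})

    ledger = GeneratorLedger(seed=seed, data={
        "protein": protein,
        "chain_map": {protein: (chain,)},
        "threshold": threshold,
        "n_links": n_links,
        "n_satisfied": n_sat,
        "n_decoys": n_decoys,
        "links": truth,
    })
    return pd.DataFrame(rows), ledger


# ---------------------------------------------------------------------------
# Docking-pose ensembles
# ---------------------------------------------------------------------------


def gen_pose_ensemble(
    n_receptor_residues: int = 120,
    site_size: int = 8,
    n_poses: int = 50,
    on_site_fraction: float = 1.0,
    seed: int = 0,
    contact_distance: float = 4.2,
    receptor: StructureModel | None = None,
    site_residues: Sequence[int] | None = None,
) -> tuple[PoseEnsemble, GeneratorLedger]:
    """A receptor plus poses concentrated at a planted binding site.

    On-site poses place one ligand pseudo-atom within 5 Å of each planted
    site residue (offset outward from the receptor centroid at
    ~*contact_distance* Å); off-site poses sit at least 15 Å from every
    receptor atom.  The ledger records the planted residues and each pose's
    class.
    """
    rng = np.random.default_rng(seed)
    if receptor is None:
        receptor = gen_globular_receptor(n_receptor_residues, seed=seed + 7919,
                                         structure_id=f"receptor{seed}")
    chain = receptor.chains()[0]
    nums, coords = receptor.ca_trace(chain)
    centroid = coords.mean(axis=0)
    r_max = float(np.max(np.linalg.norm(coords - centroid, axis=1)))

    if site_residues is None:
        # a spatially coherent patch: a seed residue plus its nearest neighbours
        anchor_i = int(rng.integers(0, len(nums)))
        d_to_anchor = np.linalg.norm(coords - coords[anchor_i], axis=1)
        site_idx = list(np.argsort(d_to_anchor)[:site_size])
    else:
        lookup = {n: i for i, n in enumerate(nums)}
        site_idx = [lookup[n] for n in site_residues]
    site_nums = [nums[i] for i in site_idx]

    n_on = int(round(n_poses * on_site_fraction))
    poses: list[StructureModel] = []
    pose_types: list[str] = []
    for p in range(n_poses):
        on_site = p < n_on
        atoms: list[AtomSite] = []
        if on_site:
            for j, i in enumerate(site_idx):
                anchor = coords[i]
                outward = anchor - centroid
                norm = np.linalg.norm(outward)
                outward = outward / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
                d = rng.uniform(contact_distance - 0.6, contact_distance + 0.4)
                jitter = rng.normal(0.0, 0.15, size=3)
                pos = anchor + outward * d + jitter
                if np.linalg.norm(pos - anchor) > 4.9:  # keep the contact guarantee
                    pos = anchor + (pos - anchor) * (4.9 / np.linalg.norm(pos - anchor))
                atoms.append(AtomSite("L", j + 1, "GLY", "CA", tuple(pos), element="C"))
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            base = centroid + direction * (r_max + 22.0)
            for j in range(len(site_idx)):
                pos = base + rng.normal(0.0, 1.0, size=3)
                atoms.append(AtomSite("L", j + 1, "GLY", "CA", tuple(pos), element="C"))
        poses.append(StructureModel(f"pose{p}", atoms))
        pose_types.append("on" if on_site else "off")

    ensemble = PoseEnsemble(receptor=receptor, poses=tuple(poses))
    ledger = GeneratorLedger(seed=seed, data={
        "site_residues": [(chain, n) for n in site_nums],
        "pose_types": pose_types,
        "n_on_site": n_on,
    })
    return ensemble, ledger


# ---------------------------------------------------------------------------
# Kinetics traces
# ---------------------------------------------------------------------------


def gen_kinetics(
    km: float = 22.81,
    vmax: float = 1.0,
    ki: float = 500.0,
    concentrations: Sequence[float] | None = None,
    noise: float = 0.0,
    constants: AssayConstants = AssayConstants(),
    seed: int = 0,
    t_max: float = 60.0,
    linear_until: float = 10.0,
    plateau_tau: float = 4.0,
    blank: float = 0.05,
    replicate: str = "r1",
) -> tuple[pd.DataFrame, GeneratorLedger]:
    """Absorbance time courses following the substrate-inhibition rate law.

    Velocities follow v = Vmax·[S]/(KM + [S]·(1+[S]/Ki)) (Ki = inf gives plain
    Michaelis–Menten).  Product formation is linear at v until *linear_until*
    minutes, then relaxes exponentially to a plateau; each accumulated-product
    reading is perturbed by multiplicative Gaussian reader noise of relative
    sd *noise* before conversion to A460 through the inverse Beer–Lambert
    relation on top of a constant blank.  Sampling is every minute up to
    *t_max*.  The ledger stores the true initial slope of every trace.
    """
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.geomspace(0.2 * km, 10.0 * km, 8)
    times = np.arange(0.0, t_max + 0.5, 1.0)

    rows, truth = [], []
    for s in concentrations:
        v_true = float(substrate_inhibition_rate(s, vmax, km, ki))
        prod = np.where(
            times <= linear_until,
            v_true * times,
            v_true * linear_until
            + v_true * plateau_tau * (1.0 - np.exp(-(times - linear_until) / plateau_tau)),
        )
        if noise > 0:
            prod = prod * (1.0 + rng.normal(0.0, noise, size=times.size))
        a460 = blank + prod * 1e-6 * constants.epsilon * constants.path_length
        for t, a in zip(times, a460):
            rows.append({"time_min": t, "A460": a, "substrate_uM": float(s),
                         "replicate": replicate})
        truth.append({"substrate_uM": float(s), "v_true": v_true, "v_realized": v_true})

    ledger = GeneratorLedger(seed=seed, data={
        "km": km, "vmax": vmax, "ki": ki,
        "constants": constants, "rates": truth,
    })
    return pd.DataFrame(rows), ledger


def traces_from_frame(df: pd.DataFrame) -> list[KineticsTrace]:
    """Group a trace table (time_min, A460, substrate_uM, replicate) into traces."""
    out = []
    for (s, rep), grp in df.groupby(["substrate_uM", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            KineticsTrace(
                substrate_conc=float(s),
                times=tuple(grp["time_min"].astype(float)),
                a460=tuple(grp["A460"].astype(float)),
                replicate=str(rep),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


def gen_abundance(
    true_copies: Mapping[str, float],
    noise_cv: float = 0.0,
    seed: int = 0,
    oligomer: Mapping[str, str] | None = None,
    base_intensity: float = 1e7,
) -> tuple[pd.DataFrame, GeneratorLedger]:
    """An iBAQ table whose intensities are proportional to planted copy numbers.

    Noise is log-normal with shape *noise_cv* (coefficient of variation for
    small values); zero noise gives exact recovery by the anchored transform.
    """
    rng = np.random.default_rng(seed)
    oligomer = dict(oligomer or {})
    rows = []
    for protein, copies in true_copies.items():
        factor = math.exp(rng.normal(0.0, noise_cv)) if noise_cv > 0 else 1.0
        rows.append({
            "protein": protein,
            "iBAQ": base_intensity * copies * factor,
            "oligomer": oligomer.get(protein, "monomer"),
        })
    ledger = GeneratorLedger(seed=seed, data={"true_copies": dict(true_copies)})
    return pd.DataFrame(rows), ledger
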