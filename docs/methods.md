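# Methods

This note documents the models implemented by the package, the parameter
choices that matter, what the synthetic generators do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## Unresolved-region survey

**Model.** A residue listed under `_pdbx_unobs_or_zero_occ_residues` in an
mmCIF file is present in the deposited sequence but missing from the
coordinates — a proxy for structural disorder. Maximal runs of consecutive
unobserved residues within one chain form a region of length *x* (amino
acids); the end-to-end Cα–Cα distance *y* (Å) between the nearest observed
residues on either side measures how far apart the structure holds the ends
of the disordered stretch.

**Conventions.** Author residue numbering is used throughout, because the
unobserved category is authored in author numbering. Only the first
coordinate model is surveyed. Zero-occupancy records are treated identically
to unobserved ones: the source category mixes both and they are
indistinguishable proxies for "not reliably placed". Alternate locations
resolve to the highest-occupancy conformer (alphabetical on ties). Regions
touching a chain terminus have only one observed flank; they are retained as
regions but excluded from distance statistics, since the end-to-end distance
requires both flanks. Whether terminal runs should count toward region
*totals* is a reporting choice; here they do.

**Binning and envelope.** Lengths 1–50 get unit-width bins; beyond 50 the
right edges are 55, 60, 65, 70, 75, 100, 125, 150, 250, 4000, reflecting the
sharp decay in the number of long regions. Per bin we report the mean
distance and quantiles 0.0–1.0 in steps of 0.2, computed by linear
interpolation between order statistics (the common default, and monotone in
the quantile level by construction).

**Saturation model.** Mean distance versus length is fit with

    y(x) = A (1 − exp(−b x)) + 3.5,

*A* (Å) the saturation amplitude above the offset, *b* (per residue) the
approach rate, and 3.5 Å a fixed additive offset of the order of one Cα–Cα
virtual bond: y(0) = 3.5 and y(∞) = A + 3.5. The offset is not fitted — it
enters the model as a constant. Fitting is unweighted nonlinear least
squares over (A, b) via `scipy.optimize.curve_fit` (optional per-bin √n
weighting is available; with unequal bin populations the unweighted fit
treats each bin as one observation of the mean curve, which is how the
binned survey is usually drawn). The abscissa of a merged bin is its
arithmetic midpoint — unbiased for symmetric bins and the least-assuming
choice given that bin contents are not retained at fitting time.
Initialisation uses A₀ = max(mean) − 3.5 and b₀ = 1/median(midpoint), with
two seeded, jittered restarts before declaring non-convergence. A survey
flat at the offset pins A to zero and flags b unidentifiable instead of
returning an arbitrary rate.

**Reference curves.** For context the package evaluates an extended
per-residue line (slope configurable; 7 Å per residue for a generous upper
reference, 3.5 Å per residue for the trans Cα–Cα contour) and three
literature power laws of the form R = R₀·N^ν for disordered chains:
Marsh & Forman-Kay (*Biophys. J.* 2010; hydrodynamic radii of IDPs,
R₀ = 2.49 Å, ν = 0.509), Wilkins et al. (*Biochemistry* 1999; denatured
states, R₀ = 2.21 Å, ν = 0.57), and a constricted-linker law in the spirit
of George & Heringa (*Protein Eng.* 2002; shipped default R₀ = 2.50 Å,
ν = 0.50). The shipped constants are package defaults for orientation —
hydrodynamic radii are not end-to-end distances — and every constant is
overridable per call; conclusions should never hinge on them.

## Crosslink mapping and satisfaction

Ledgers are deduplicated on the unordered ((protein, residue), (protein,
residue)) pair across replicates, with replicate provenance retained as
metadata; self-pairs and unparseable rows are skipped and counted. Mapping
takes the minimum Cα–Cα distance over all chain assignments permitted by the
protein→chains map — the standard resolution of homo-oligomer ambiguity —
and leaves a link UNMAPPED (data, not an error) when no candidate chain
carries both Cα atoms. Distances are Cα–Cα rather than side-chain NZ–NZ,
matching the survey convention; the satisfaction cutoff defaults to 30 Å
(BS3: 11.4 Å spacer + two lysine side chains + backbone tolerance) and is
inclusive at the boundary. Because published satisfaction percentages rarely
state their cutoff, reports always carry the 25/30/35 Å profile. Distance
distributions are fit as log-normals by maximum likelihood (mean and sd of
log distances) with a one-sample Kolmogorov–Smirnov statistic against the
fitted distribution as the goodness-of-fit summary.

## Interface frequencies and hotspots

A receptor residue contacts a pose when any of its heavy atoms lies within
5 Å of any ligand heavy atom; hydrogens are excluded because their presence
varies across refined models. The neighbour search uses a k-d tree
(`scipy.spatial.cKDTree`) and is exact — the test suite checks bit-identical
agreement with the all-pairs distance scan. Counts over the ensemble,
divided by the number of poses, give frequencies in [0, 1]. "Top quartile
(above 25%)" admits two readings, both shipped: (A, default) frequency at or
above the 75th percentile of the *nonzero* frequencies, ties at the
percentile included (so a flat table returns every contacting residue); (B)
frequency strictly above 0.25 of poses. The default is A because it adapts
to ensembles where even true hotspots fall below a fixed pose fraction.

## Kinetics

Absorbance converts to product concentration as c = A/(ε·l), with
ε = 3.07 × 10⁴ M⁻¹ cm⁻¹ for the WST-8 formazan. The optical path length *l*
is **assumed 1 cm** and configurable: plate formats differ and the true path
is a property of the instrument and fill volume; every report repeats this
caveat. The first timepoint serves as a per-trace blank, making velocities
invariant to constant absorbance offsets.

**Initial velocities.** v₀ is the ordinary-least-squares slope of
concentration versus time over the longest prefix window (≥ 5 points) whose
quadratic refit shows no statistically significant curvature (|t| of the
quadratic coefficient < 3). A plain R² ≥ 0.99 prefix rule was considered and
rejected: on traces that plateau, windows two or three points into the
plateau still exceed R² = 0.99 while depressing the slope by 5–10%, and on
noisy-but-linear traces R² dips below 0.99 by chance; the curvature test
separates exactly these two cases (zero-residual linear prefixes are always
accepted, the first plateau point makes the quadratic term significant).

**Michaelis constant.** Under substrate-excess inhibition,

    v = Vmax·[S] / (KM + [S]·(1 + [S]/Ki)),

the double-reciprocal plot of 1/v against 1/[S] is linear only in the
asymptotic low-[S] regime. The fit regresses 1/v on 1/[S] over the k
lowest-concentration points (k = max(3, ⌊n/2⌋) by default), then
KM = slope/intercept and Vmax = 1/intercept; a non-positive slope or
intercept means the abscissa crossing is not at negative 1/[S] —
inhibition-dominated data — and raises. At Ki → ∞ every point lies on one
line and the fit reduces to the plain Michaelis–Menten estimate (tested).
Known behaviour: when Ki is within a few-fold of KM, residual inhibition
inside the asymptotic subset biases KM low; this is a property of the
double-reciprocal construction itself, and the package reports which points
entered the fit so the bias is auditable.

## Stoichiometry

iBAQ scores are treated as proportional to copy number within one sample;
anchoring one subunit to a known copy count (the 24-mer core) converts
ratios to copies: copiesᵢ = 24 · iBAQᵢ/iBAQ_anchor. The transform is linear
by design — the precedent analyses it follows are qualitative, and no
rounding is applied to raw copies. Assembly units divide copies by the
oligomeric state (monomer/dimer). Maximal occupancy is plain arithmetic:
core monomers + tether monomers + two chains per tethered dimer.

## Synthetic generators

Every generator is a deterministic function of (parameters, seed), returns a
ground-truth ledger, and writes the same formats the pipeline reads.

* **Structures.** Cα traces are 3.8 Å-step random walks with uniformly
  random step directions; selected internal segments move to the unobserved
  category with at least one observed residue flanking and separating gaps.
  Coordinates are rounded to 10⁻⁴ Å *before* ledger distances are computed,
  so file round trips reproduce the ledger to 10⁻⁹ Å. The walks are not
  self-avoiding; excluded volume is irrelevant to the end-to-end and contact
  statistics exercised here, but it means the chains are not physically
  realistic proteins.
* **Survey points.** Per-bin means drawn from the saturation model at bin
  midpoints plus Gaussian noise (default experiment: A = 11 Å, b = 0.2 per
  residue, sd 0.3 Å, bins to length 250).
* **Crosslinks.** Residue pairs are sampled from the model's true distance
  matrix so that exactly round(n·f) pairs fall at or below the threshold;
  decoys reference absent residues to exercise the UNMAPPED path.
* **Pose ensembles.** The default receptor is a quasi-uniform spherical
  shell of Cα pseudo-residues (Fibonacci lattice, ~6 Å spacing) — a coarse
  globular surface without the fold-backs of a random walk, so a planted
  contact patch is spatially separable. On-site poses place one ligand
  pseudo-atom within 5 Å of each planted residue (outward offset ~4.2 Å with
  jitter, clamped to preserve the contact guarantee); off-site poses sit
  ≥ 15 Å from every receptor atom. Real docking ensembles have full side
  chains, partial overlaps and correlated poses; recovery results here show
  the *scoring* logic is correct, not that real ensembles are this clean.
* **Kinetics.** Product accumulates linearly at the substrate-inhibition
  rate for 10 min, then relaxes exponentially (τ = 4 min) to a plateau;
  readings carry multiplicative Gaussian reader noise (default 5%) and a
  constant blank, converted to A460 through the inverse Beer–Lambert
  relation. Default titration: 8 concentrations spanning 0.2–10×KM; the
  CoA-like condition is KM = 22.81 µM with Ki = 500 µM.
* **Abundances.** iBAQ ∝ planted copies with log-normal noise.

## Numerical choices and degenerate inputs

Superposition uses the Kabsch SVD construction with the determinant
correction to guarantee a proper rotation; rank-deficient (collinear) or
< 3-point inputs raise. Rotation angles come from the matrix trace,
clamped into [−1, 1] before arccos. The signed trimer displacement is the
intra-structure align→target rotation angle of the second structure minus
the first — antisymmetric by construction and invariant to global rigid
motions, which is why the pre-alignment on the reference chain cannot change
it. Quantiles, satisfaction fractions and hotspot thresholds all define
their boundary behaviour inclusively and are covered by boundary tests.

## Problem sizes

The shipped experiments use 40 structures × 8 gaps for the structure-level
survey, 20 seeds for fit-recovery and KM-recovery medians, 300–400 planted
crosslinks, and a 400-pose × 500-residue ensemble — sizes chosen so every
driver and the full test suite run in seconds on one CPU while leaving each
estimator enough data to exhibit its statistical behaviour. The survey
batch mode accepts arbitrarily many mmCIF files for archive-scale runs.

## Known limitations

* The linker survey treats every unobserved region as disorder; missing
  density has other causes (radiation damage, weak crystal contacts), which
  a synthetic generator cannot emulate.
* Satisfaction percentages depend on the cutoff convention; compare profiles,
  not single numbers.
* The asymptotic Lineweaver–Burk KM inherits the reciprocal transform's
  noise amplification at low [S] and the inhibition bias noted above;
  a direct nonlinear fit of the rate law would be statistically preferable
  but is deliberately out of scope — the point is to reproduce the assay's
  own analysis.
* iBAQ-to-copies anchoring assumes equal detectability across subunits;
  the estimates are qualitative bands, not absolute quantitation.
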