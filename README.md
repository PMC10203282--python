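# metabolon

Analysis pipeline for the bespoke computations behind a structural and
kinetic dissection of a native oxoglutarate dehydrogenase complex (OGDHc)
metabolon: a 24-mer E2o (dihydrolipoyl succinyltransferase) cubic core whose
flexible N-terminal arms tether peripheral E1o and E3 dimers and shuttle a
lipoyl domain (LD) between their active sites.

The package is aimed at structural bioinformaticians and biochemists who
want each of those computations as tested, importable library code,
exercisable on synthetic inputs with known ground truth — no downloads, no
deposited maps.

## What it computes

* **Unresolved-linker distance survey** (`metabolon.structure_io`,
  `metabolon.linker_survey`). Unmodelled polymer stretches are read from the
  `_pdbx_unobs_or_zero_occ_residues` category of mmCIF files, merged into
  maximal regions, and the end-to-end Cα–Cα distance *y* between the observed
  flanking residues is measured. Distances are pooled into adaptive length
  bins (unit width for 1–50 residues, then right edges 55, 60, 65, 70, 75,
  100, 125, 150, 250, 4000), summarised as means with a quantile envelope
  (q = 0.0…1.0 in steps of 0.2), and fit with the empirical saturation model

  ```
  y(x) = A (1 − e^(−b·x)) + 3.5  [Å],
  ```

  with the 3.5 Å offset fixed. On surveys of deposited structures the
  constants come out near A ≈ 11 Å and b ≈ 0.2 per residue — flanking
  residues stay dramatically confined however long the missing stretch.
  Reference curves (an extended per-residue line and literature power laws
  for disordered chains) are provided for comparison.

* **Crosslink validation** (`metabolon.xlink`). Crosslink ledgers are
  deduplicated on unordered residue pairs, mapped onto models as minimum
  Cα–Cα distances over allowed chain assignments, and summarised as
  satisfaction fractions (cutoff defaults to 30 Å, the BS3 convention, and is
  always reported alongside 25/35 Å), log-normal distance-distribution fits
  with a Kolmogorov–Smirnov statistic, and per-protein link counts.

* **Guiding-surface extraction** (`metabolon.interface_freq`). Per-residue
  contact frequencies of a receptor over an ensemble of docked ligand poses
  (heavy-atom proximity within 5 Å), with top-quartile hotspot extraction
  under both readings of "top quartile": the 75th percentile of nonzero
  frequencies (default) or contact in more than 25% of poses.

* **Michaelis constants under substrate-excess inhibition**
  (`metabolon.kinetics`). WST-8 absorbance traces are converted to product
  concentrations via Beer–Lambert (ε = 3.07 × 10⁴ M⁻¹ cm⁻¹), initial
  velocities are slopes over the longest early window free of significant
  curvature, and KM is read off the abscissa intersection of the asymptotic
  (low-[S]) Lineweaver–Burk regression, since v = Vmax·[S]/(KM + [S]·(1+[S]/Ki))
  bends the reciprocal line at high [S].

* **iBAQ-anchored stoichiometry** (`metabolon.stoichiometry`). Relative iBAQ
  abundances become copy numbers by anchoring to the fixed 24-copy E2o core;
  maximal-occupancy arithmetic (24 core + 24 tethers + 2×12 + 2×12 dimer
  chains = 96) bounds the metabolon's chain count.

* **Synthetic data with ledgers** (`metabolon.synthetic`). Every input above
  can be generated with known ground truth: Cα traces with excised segments,
  crosslink ledgers with planted satisfied fractions, pose ensembles
  clustered at planted sites, substrate-inhibition titrations, abundance
  tables. Generators are byte-reproducible functions of their seed.

## Worked example

Simulate a structure with six excised segments, survey it, and fit the
saturation model:

```sh
$ metabolon simulate structure --seed 7 --out s7.cif
wrote s7.cif (6 gap(s), seed 7)
$ metabolon survey --cif s7.cif --out survey_out
fit: A=10.460 Å, b=0.6685 per residue (6 bins)
```

The survey table, fit JSON and envelope plot land in `survey_out/`. A single
random-walk structure gives only six bins, hence the rough constants; the
analysis driver below runs the fit-recovery experiment at scale. Kinetics,
end to end:

```sh
$ metabolon simulate kinetics --seed 1 --out traces.csv
wrote traces.csv (true KM 22.81 µM, Ki 500.0 µM)
$ metabolon kinetics --traces traces.csv --out kin_out
KM = 19.46 µM, Vmax = 0.842 µM/min (4 asymptotic points)
```

The fitted 19.5 µM sits within the recovery error expected from an
asymptotic double-reciprocal fit of noisy substrate-inhibition data (the
analysis driver quantifies it at ~15% median over seeds).

The numbered drivers under `analysis/` run each stage at study scale and
write tables under `results/`:

```sh
python analysis/01_linker_survey.py
# fit recovery over 20 noisy surveys: median A = 11.006 Å (truth 11),
# median b = 0.2014 per residue (truth 0.2)
python analysis/05_stoichiometry.py
# E2o: 24.00 copies (24) ... estimated chains 54.7 vs maximal occupancy 96
```

## Layout

```
src/metabolon/      library modules (structure_io, linker_survey, xlink,
                    interface_freq, kinetics, stoichiometry, synthetic,
                    plots, cli)
analysis/           numbered narrative drivers over the library
scripts/            acceptance recomputation
tests/              pytest suite (unit, property, end-to-end)
docs/methods.md     models, assumptions, parameter choices, limitations
```
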