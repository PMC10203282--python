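#!/usr/bin/env python
"""Michaelis constants under substrate-excess inhibition.

Generates WST-8 absorbance titrations for the three soluble substrates at
their in-fraction Michaelis constants (α-ketoglutarate 149.80 µM, NAD+
146.11 µM, CoA 22.81 µM; substrate-excess inhibition with Ki = 500 µM),
extracts initial velocities from the early-linear windows, and determines KM
from the asymptotic double-reciprocal regression.  A 20-seed replicate of
the CoA titration quantifies recovery error.

Writes: results/kinetics/{rates_<substrate>.tsv,km_fits.json,lineweaver_burk_coa.svg}
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from metabolon.kinetics import initial_velocity, lineweaver_burk_km, normalize_velocities
from metabolon.plots import lineweaver_burk_plot
from metabolon.synthetic import gen_kinetics, traces_from_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "kinetics"
OUT.mkdir(parents=True, exist_ok=True)

# true KM (µM), inhibition constant (µM), titration range (µM) per substrate;
# Ki for the high-KM substrates sits near the top of their titration so the
# velocity decline appears within the measured range, as for CoA
SUBSTRATES = {
    "akg": (149.80, 3000.0, (50.0, 5000.0)),
    "nad": (146.11, 3000.0, (25.0, 5000.0)),
    "coa": (22.81, 500.0, (5.0, 1000.0)),
}

fits = {}
for name, (km_true, ki, (lo, hi)) in SUBSTRATES.items():
    concs = np.geomspace(lo, hi, 8)
    df, ledger = gen_kinetics(km=km_true, vmax=1.0, ki=ki,
                              concentrations=concs, noise=0.05, seed=1)
    rates = [initial_velocity(t) for t in traces_from_frame(df)]
    fit = lineweaver_burk_km(rates)
    fits[name] = {"km_uM": fit.km, "true_km_uM": km_true, "ki_uM": ki, "vmax": fit.vmax}
    print(f"{name:>4s}: fitted KM = {fit.km:7.2f} µM (truth {km_true:7.2f} µM)")
    normed = normalize_velocities(rates)
    pd.DataFrame([
        {"substrate_uM": r.substrate_conc, "v0": orig.v0, "v0_norm": r.v0, "r2": orig.r2}
        for orig, r in zip(rates, normed)
    ]).to_csv(OUT / f"rates_{name}.tsv", sep="\t", index=False)
    if name == "coa":
        lineweaver_burk_plot(rates, fit, path=str(OUT / "lineweaver_burk_coa.svg"))

errs = []
for seed in range(20):
    df, ledger = gen_kinetics(km=22.81, vmax=1.0, ki=500.0, noise=0.05, seed=seed)
    rates = [initial_velocity(t) for t in traces_from_frame(df)]
    errs.append(abs(lineweaver_burk_km(rates).km - 22.81) / 22.81)
med = float(np.median(errs))
print(f"CoA KM recovery over 20 seeds: median relative error {med:.1%}")
print("note: when Ki is within a few-fold of KM (akg/nad here), residual "
      "inhibition inside the asymptotic subset biases KM low — the price of "
      "the double-reciprocal construction the assay prescribes")

(OUT / "km_fits.json").write_text(json.dumps({
    "fits": fits,
    "coa_recovery_median_rel_error": med,
    "noise": 0.05,
    "note": "optical path length assumed 1 cm; configure for your plate format",
}, indent=2) + "\n")
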