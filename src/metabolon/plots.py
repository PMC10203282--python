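"""Plotting helpers for survey, kinetics and interface reports."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .interface_freq import ContactFrequencyTable
from .kinetics import KMFit, RateRecord
from .linker_survey import QUANTILES, BinSummary, SaturationFit, saturation_model


def survey_envelope_plot(summaries: Sequence[BinSummary], fit: SaturationFit | None = None,
                         path: str | None = None):
    """Mean distance per bin with the quantile envelope and the model overlay."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    x = np.array([s.midpoint for s in summaries])
    mean = np.array([s.mean_distance for s in summaries])
    shades = [(0.0, 1.0), (0.2, 0.8), (0.4, 0.6)]
    for k, (ql, qh) in enumerate(shades):
        lo = np.array([s.quantile_distances[ql] for s in summaries])
        hi = np.array([s.quantile_distances[qh] for s in summaries])
        ax.fill_between(x, lo, hi, color="0.5", alpha=0.18 + 0.12 * k,
                        label=f"q{ql:.1f}-q{qh:.1f}")
    ax.plot(x, mean, "ko", ms=3, label="bin mean")
    if fit is not None and fit.b_identifiable:
        xs = np.linspace(max(x.min(), 0.0), x.max(), 400)
        ax.plot(xs, saturation_model(xs, fit.A, fit.b, fit.offset), "r-",
                label=f"A(1-e^(-bx))+{fit.offset:g}, A={fit.A:.2f}, b={fit.b:.3f}")
    ax.set_xscale("log")
    ax.set_xlabel("unresolved-region length (aa)")
    ax.set_ylabel("end-to-end Cα–Cα distance (Å)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def lineweaver_burk_plot(rates: Sequence[RateRecord], fit: KMFit, path: str | None = None):
    """Double-reciprocal plot with the asymptotic regression line."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    inv_s = np.array([1.0 / r.substrate_conc for r in rates])
    inv_v = np.array([1.0 / r.v0 for r in rates])
    used = {id(r) for r in fit.points_used}
    in_fit = np.array([id(r) in used for r in rates])
    ax.plot(inv_s[~in_fit], inv_v[~in_fit], "o", mfc="none", color="0.6",
            label="excluded (inhibition regime)")
    ax.plot(inv_s[in_fit], inv_v[in_fit], "ko", label="asymptotic subset")
    xs = np.linspace(-1.2 / fit.km, inv_s.max() * 1.05, 100)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-",
            label=f"KM={fit.km:.1f} µM, Vmax={fit.vmax:.3g}")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("1/[S] (µM⁻¹)")
    ax.set_ylabel("1/v (min·µM⁻¹)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def frequency_bar_plot(table: ContactFrequencyTable, hotspot_set=None, path: str | None = None):
    """Per-residue contact frequencies with hotspots highlighted."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    freqs = table.frequencies
    labels = [f"{c}{n}" for c, n in table.residues]
    colors = ["tab:blue" if (hotspot_set and r in hotspot_set) else "0.7"
              for r in table.residues]
    ax.bar(range(len(freqs)), freqs, color=colors)
    step = max(1, len(labels) // 40)
    ax.set_xticks(range(0, len(labels), step))
    ax.set_xticklabels(labels[::step], rotation=90, fontsize=6)
    ax.set_ylabel("contact frequency")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
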