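"""Enzyme kinetics from plate-reader absorbance under substrate-excess inhibition.

The activity assay follows formazan formation by WST-8 at 460 nm; absorbance
is converted to product concentration with the Beer–Lambert law (molar
absorption coefficient ε = 3.07 × 10⁴ M⁻¹ cm⁻¹; path length defaults to 1 cm
and must be overridden for plate formats with a different optical path).
Initial velocities are ordinary-least-squares slopes over the longest early
time window that remains linear (prefix window of at least 5 points showing
no statistically significant curvature), after subtracting the
first-timepoint blank.

Because velocity declines again at high substrate (substrate-excess
inhibition, v = Vmax·[S]/(KM + [S]·(1+[S]/Ki))), the Michaelis constant is
determined on the double-reciprocal (Lineweaver–Burk) plot from the
*asymptotic* linear regression: the fit is restricted to the low-[S]
(high 1/[S]) subset, where the inhibition term vanishes, and KM is read off
the abscissa intersection (KM = −1/x-intercept = slope/intercept).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class AssayConstants:
    """Beer–Lambert constants of the WST-8 readout."""

    epsilon: float = 3.07e4  # M^-1 cm^-1, molar absorption of WST-8 formazan
    path_length: float = 1.0  # cm; plate-format paths differ — configure it

    def __post_init__(self):
        if self.epsilon <= 0 or self.path_length <= 0:
            raise ValueError("epsilon and path_length must be positive")


@dataclass(frozen=True)
class KineticsTrace:
    """One absorbance time course at a fixed substrate concentration."""

    substrate_conc: float  # µM
    times: tuple[float, ...]  # minutes
    a460: tuple[float, ...]
    replicate: str = "r1"

    def __post_init__(self):
        if len(self.times) != len(self.a460):
            raise ValueError("times and a460 must have equal length")
        t = np.asarray(self.times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.a460)):
            raise ValueError("absorbances must be finite")


@dataclass(frozen=True)
class RateRecord:
    """Initial velocity extracted from one trace."""

    substrate_conc: float  # µM
    v0: float  # µM / min
    fit_window: tuple[float, float]
    r2: float
    replicate: str = "r1"


@dataclass(frozen=True)
class KMFit:
    """Double-reciprocal asymptotic fit."""

    km: float  # µM
    vmax: float  # µM / min
    slope: float
    intercept: float
    points_used: tuple[RateRecord, ...]


def absorbance_to_concentration(
    a460,
    constants: AssayConstants = AssayConstants(),
    blank_tolerance: float = 0.01,
):
    """Beer–Lambert conversion of A460 to product concentration in µM.

    Negative absorbances beyond *blank_tolerance* trigger a warning; all
    negatives are clipped at zero.
    """
    a = np.asarray(a460, dtype=float)
    if np.any(a < -blank_tolerance):
        warnings.warn(
            f"absorbance below -{blank_tolerance} encountered; clipping at 0",
            stacklevel=2,
        )
    c_molar = np.clip(a, 0.0, None) / (constants.epsilon * constants.path_length)
    c_um = c_molar * 1e6
    return float(c_um) if np.isscalar(a460) else c_um


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² (R² of a perfectly flat, perfectly fit line is 1)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-30:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def _curvature_t(x: np.ndarray, y: np.ndarray) -> float:
    """t-statistic of the quadratic coefficient of a degree-2 fit (0 for a perfect line)."""
    X = np.column_stack([np.ones_like(x), x, x**2])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(x) - 3
    if dof <= 0:
        return 0.0
    s2 = float(resid @ resid) / dof
    if s2 <= 1e-24:
        # perfect quadratic fit: flag any true curvature, accept a true line
        return 0.0 if abs(coef[2]) <= 1e-12 else math.inf
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(coef[2] / math.sqrt(cov[2, 2]))


def initial_velocity(
    trace: KineticsTrace,
    constants: AssayConstants = AssayConstants(),
    min_points: int = 5,
    curvature_t_max: float = 3.0,
) -> RateRecord:
    """Initial velocity as the OLS slope over the longest early-linear window.

    The first timepoint serves as a per-trace blank; prefix windows of at
    least *min_points* are scanned and the longest without statistically
    significant curvature wins (|t| of the quadratic term below
    *curvature_t_max*).  Product depletion or plateau onset makes the
    quadratic term significant and truncates the window at the linear phase;
    a constant offset on all absorbances leaves v0 unchanged.
    """
    if len(trace.times) < min_points:
        raise ValueError(f"trace has fewer than {min_points} timepoints")
    t = np.asarray(trace.times, dtype=float)
    a = np.asarray(trace.a460, dtype=float) - trace.a460[0]
    conc = absorbance_to_concentration(a, constants)

    best: tuple[int, float, float] | None = None  # (end, slope, r2)
    for end in range(min_points, len(t) + 1):
        if abs(_curvature_t(t[:end], conc[:end])) < curvature_t_max:
            slope, _, r2 = _ols(t[:end], conc[:end])
            best = (end, slope, r2)
    if best is None:
        raise ValueError(
            f"no prefix window of >= {min_points} points is free of significant curvature"
        )
    end, slope, r2 = best
    return RateRecord(
        substrate_conc=trace.substrate_conc,
        v0=slope,
        fit_window=(float(t[0]), float(t[end - 1])),
        r2=r2,
        replicate=trace.replicate,
    )


def lineweaver_burk_km(
    rates: Sequence[RateRecord],
    n_asymptotic: int | None = None,
) -> KMFit:
    """KM and Vmax from the asymptotic double-reciprocal regression.

    1/v is regressed on 1/[S] over the *n_asymptotic* lowest-concentration
    points (default ``max(3, n // 2)``), where the substrate-inhibition term
    is negligible; KM = slope/intercept and Vmax = 1/intercept.  A
    non-positive y-intercept means the abscissa crossing lies at positive
    1/[S] — inhibition-dominated data — and is an error.
    """
    rates = [r for r in rates]
    if len({r.substrate_conc for r in rates}) < 3:
        raise ValueError("KM fit requires rates at >= 3 distinct concentrations")
    if any(r.substrate_conc <= 0 or r.v0 <= 0 for r in rates):
        raise ValueError("concentrations and velocities must be positive on a reciprocal plot")
    k = n_asymptotic if n_asymptotic is not None else max(3, len(rates) // 2)
    k = min(max(k, 3), len(rates))
    subset = sorted(rates, key=lambda r: r.substrate_conc)[:k]
    inv_s = np.array([1.0 / r.substrate_conc for r in subset])
    inv_v = np.array([1.0 / r.v0 for r in subset])
    slope, intercept, _, _, _ = stats.linregress(inv_s, inv_v)
    if intercept <= 0 or slope <= 0:
        raise ValueError(
            "the reciprocal line has no abscissa crossing at negative 1/[S] "
            "(non-positive slope or intercept); data appear inhibition-dominated "
            "even in the asymptotic subset"
        )
    return KMFit(
        km=float(slope / intercept),
        vmax=float(1.0 / intercept),
        slope=float(slope),
        intercept=float(intercept),
        points_used=tuple(subset),
    )


def normalize_velocities(rates: Sequence[RateRecord]) -> list[RateRecord]:
    """Velocities rescaled to [0, 1] by the maximum; ordering preserved."""
    if not rates:
        raise ValueError("no rates to normalize")
    vmax = max(r.v0 for r in rates)
    if vmax <= 0:
        raise ValueError("all velocities are zero; normalization undefined")
    return [
        RateRecord(r.substrate_conc, r.v0 / vmax, r.fit_window, r.r2, r.replicate)
        for r in rates
    ]


def substrate_inhibition_rate(s, vmax: float, km: float, ki: float = math.inf):
    """v = Vmax·[S] / (KM + [S]·(1 + [S]/Ki)); Ki = inf reduces to Michaelis–Menten."""
    s = np.asarray(s, dtype=float)
    denom = km + s * (1.0 + (s / ki if math.isfinite(ki) else 0.0))
    return vmax * s / denom
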