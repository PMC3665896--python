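"""Michaelis-Menten substrate-affinity fits for permeabilized fibres.

A stepwise substrate titration at one assay temperature yields a
(concentration, respiration rate) series; the apparent affinity K_m,app
and V_max come from unweighted nonlinear least squares on

    v(c) = Vmax * c / (Km + c)

initialised by a Hanes-Woolf linearization (c/v regressed on c).  The
efficiency Vmax / K_m,app (a k_cat/K_m analogue) summarises how well the
fibres exploit physiological substrate levels; fold changes against a
reference temperature expose thermal loss of affinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class TitrationSeries:
    concentrations: np.ndarray      # uM, strictly increasing
    rates: np.ndarray               # pmol O2 s^-1 mg^-1
    substrate: str = "pyruvate"
    temperature: float = 20.0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if c.size == 0:
            raise ValueError("empty titration series")
        if c.size != r.size:
            raise ValueError("concentrations and rates differ in length")
        if np.any(c < 0):
            raise ValueError("negative concentration")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        self.concentrations = c
        self.rates = r


@dataclass
class MMFit:
    km_app: float                   # uM
    vmax: float
    km_se: float
    vmax_se: float
    efficiency: float               # vmax / km_app
    r2: float
    flags: list[str] = field(default_factory=list)


def _mm(c, vmax, km):
    return vmax * c / (km + c)


def fit_mm(series: TitrationSeries, init_strategy: str = "hanes") -> MMFit:
    """Fit v = Vmax*c/(Km+c); Hanes-Woolf start, SEs from the covariance.

    A ``NON_SATURATED`` flag is raised (fit still returned) when the
    highest concentration does not exceed the fitted Km.
    """
    c = series.concentrations
    v = series.rates
    if c.size < 5:
        raise ValueError("fit_mm needs >= 5 points")
    if np.ptp(v) == 0:
        raise ValueError("rates are all equal; nothing to fit")

    if init_strategy == "hanes":
        mask = (c > 0) & (v > 0)
        if mask.sum() >= 2:
            slope, intercept = np.polyfit(c[mask], c[mask] / v[mask], 1)
            vmax0 = 1.0 / slope if slope > 0 else float(v.max())
            km0 = intercept * vmax0 if intercept > 0 else float(np.median(c))
        else:
            vmax0, km0 = float(v.max()), float(np.median(c))
    else:
        vmax0, km0 = float(v.max()), float(np.median(c))
    vmax0 = max(vmax0, 1e-12)
    km0 = max(km0, 1e-12)

    try:
        popt, pcov = optimize.curve_fit(
            _mm, c, v, p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"Michaelis-Menten fit failed: {err}") from err
    vmax, km = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    resid = v - _mm(c, *popt)
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    flags = []
    if float(c.max()) < km:
        flags.append("NON_SATURATED")
    return MMFit(km_app=float(km), vmax=float(vmax),
                 km_se=float(perr[1]), vmax_se=float(perr[0]),
                 efficiency=float(vmax / km), r2=float(r2), flags=flags)


def efficiency_table(fits_by_temperature: dict[float, MMFit],
                     reference_temperature: float) -> pd.DataFrame:
    """Km / Vmax / efficiency per temperature with reference fold changes."""
    if len(fits_by_temperature) < 2:
        raise ValueError("efficiency_table needs >= 2 temperatures")
    if reference_temperature not in fits_by_temperature:
        raise KeyError(f"reference {reference_temperature} missing")
    ref = fits_by_temperature[reference_temperature]
    rows = []
    for T in sorted(fits_by_temperature):
        f = fits_by_temperature[T]
        rows.append((T, f.km_app, f.vmax, f.efficiency,
                     f.km_app / ref.km_app, f.vmax / ref.vmax,
                     f.efficiency / ref.efficiency))
    return pd.DataFrame(rows, columns=[
        "temperature", "km_app", "vmax", "efficiency",
        "km_fold", "vmax_fold", "efficiency_fold"]).set_index("temperature")
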