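"""SUIT respiratory states and the coupling / membrane-integrity indices.

A substrate-uncoupler-inhibitor titration (SUIT) probes distinct
respiratory states in a single assay.  The canonical sequence is

    Mal, Pyr (Leak-I) -> ADP (OXP-I with pyruvate+malate) -> Glu (OXP-I)
    -> Cyt c (outer-membrane test) -> Succ (OXP-I,II) -> NADH
    (inner-membrane test) -> Atr (Leak-I,II) -> FCCP x n (ETS, taken as
    the maximum across uncoupler steps) -> Rot, Malo, Ant (inhibition)
    -> TMPD+Asc (CCO).

From the per-state fluxes the coupling and integrity indices follow:

    RCR   = OXP-I / Leak-I          (respiratory control ratio)
    UCR   = ETS / OXP-I,II          (uncoupled control ratio)
    RCR2  = OXP-I,II / Leak-I,II    (inner-membrane permeability proxy)
    FCR   = Leak-I,II / ETS         (flux control ratio)
    cytc_frac = Cyt c / OXP-I - 1   (outer-membrane damage)
    nadh_frac = NADH / OXP-I,II - 1 (inner-membrane damage)

plus CCO relative to OXP-I,II and to ETS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .flux import IntervalFlux
from .io import AssayMeta
from . import stats as mstats

#: State vocabulary, in canonical titration order (ETS spans FCCP steps).
STATE_ORDER = ["LeakI", "OXPI_pm", "OXPI", "CytC", "OXPI_II", "NADH",
               "LeakI_II", "ETS", "CCO"]

#: Event that opens each state's interval.  Leak-I needs both malate and
#: pyruvate present; ETS is the max across repeated FCCP additions.
_STATE_EVENT = {"OXPI_pm": "ADP", "OXPI": "Glu", "CytC": "Cytc",
                "OXPI_II": "Succ", "NADH": "NADH", "LeakI_II": "Atr",
                "CCO": "TMPD+Asc"}

RATIO_NAMES = ["RCR", "UCR", "RCR2", "FCR", "CCO_over_OXPI_II",
               "CCO_over_ETS", "cytc_frac", "nadh_frac"]


@dataclass
class StateTable:
    fluxes: dict[str, float]
    meta: AssayMeta = field(default_factory=AssayMeta)
    issues: list[str] = field(default_factory=list)

    def __getitem__(self, state: str) -> float:
        return self.fluxes[state]

    def get(self, state: str, default=None):
        return self.fluxes.get(state, default)


@dataclass
class RatioTable:
    ratios: dict[str, float]
    issues: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.ratios[name]

    def get(self, name: str, default=None):
        return self.ratios.get(name, default)


def assign_states(interval_fluxes: list[IntervalFlux],
                  meta: AssayMeta | None = None) -> StateTable:
    """Map titration intervals to named respiratory states.

    Leak-I is the interval opened by the later of malate and pyruvate
    (before ADP); ETS is the maximum flux across FCCP steps.  Missing
    events yield absent states, each flagged; canonical events appearing
    out of order raise a ``PROTOCOL_ORDER`` issue.
    """
    issues: list[str] = []
    fluxes: dict[str, float] = {}
    by_label: dict[str, list[tuple[int, IntervalFlux]]] = {}
    for i, iv in enumerate(interval_fluxes):
        by_label.setdefault(iv.label, []).append((i, iv))

    positions: dict[str, int] = {}

    # Leak-I: later of Mal / Pyr, both present, before any ADP
    if "Mal" in by_label and "Pyr" in by_label:
        i_mal = by_label["Mal"][0][0]
        i_pyr = by_label["Pyr"][0][0]
        i_leak = max(i_mal, i_pyr)
        fluxes["LeakI"] = interval_fluxes[i_leak].flux
        positions["LeakI"] = i_leak
    else:
        issues.append("MISSING_STATE:LeakI")

    for state, label in _STATE_EVENT.items():
        if label in by_label:
            i, iv = by_label[label][0]
            fluxes[state] = iv.flux
            positions[state] = i
        else:
            issues.append(f"MISSING_STATE:{state}")

    if "FCCP" in by_label:
        steps = [iv.flux for _, iv in by_label["FCCP"]]
        fluxes["ETS"] = max(steps)
        positions["ETS"] = by_label["FCCP"][0][0]
    else:
        issues.append("MISSING_STATE:ETS")

    present = [s for s in STATE_ORDER if s in positions]
    pos = [positions[s] for s in present]
    if any(b <= a for a, b in zip(pos, pos[1:])):
        issues.append("PROTOCOL_ORDER")

    return StateTable(fluxes=fluxes,
                      meta=meta or AssayMeta(), issues=issues)


def ratio_suite(state_table: StateTable) -> RatioTable:
    """The full coupling / integrity ratio suite from a state table.

    Ratios whose states are absent are omitted; a zero denominator
    yields an undefined (NaN) ratio with an issue code.
    """
    s = state_table.fluxes
    defs = {
        "RCR": ("OXPI", "LeakI"),
        "UCR": ("ETS", "OXPI_II"),
        "RCR2": ("OXPI_II", "LeakI_II"),
        "FCR": ("LeakI_II", "ETS"),
        "CCO_over_OXPI_II": ("CCO", "OXPI_II"),
        "CCO_over_ETS": ("CCO", "ETS"),
    }
    ratios: dict[str, float] = {}
    issues: list[str] = []
    for name, (num, den) in defs.items():
        if num in s and den in s:
            if s[den] == 0:
                ratios[name] = math.nan
                issues.append(f"ZERO_DENOMINATOR:{name}")
            else:
                ratios[name] = s[num] / s[den]
    for name, num, den in [("cytc_frac", "CytC", "OXPI"),
                           ("nadh_frac", "NADH", "OXPI_II")]:
        if num in s and den in s:
            if s[den] == 0:
                ratios[name] = math.nan
                issues.append(f"ZERO_DENOMINATOR:{name}")
            else:
                ratios[name] = s[num] / s[den] - 1.0
    return RatioTable(ratios=ratios, issues=issues)


def integrity_test(fractions_across_fish: dict, alpha: float = 0.05
                   ) -> pd.DataFrame:
    """One-sample t of membrane-integrity fractions against zero.

    ``fractions_across_fish`` maps temperature (or condition) to the
    per-fish fractional increases; a significant positive mean indicates
    membrane damage at that temperature.
    """
    rows = []
    for key, vals in fractions_across_fish.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            raise ValueError("integrity_test needs n >= 3 fish per level")
        t, p, sig = mstats.one_sample_t(v, 0.0, alpha=alpha)
        rows.append((key, float(v.mean()),
                     float(v.std(ddof=1) / np.sqrt(v.size)), t, p, sig))
    return pd.DataFrame(rows, columns=["level", "mean", "sem", "t", "p",
                                       "significant"]).set_index("level")


def percent_increase(flux_by_temperature: pd.DataFrame,
                     reference_temperature: float) -> pd.DataFrame:
    """Percentage increase of each state's flux over the reference.

    ``flux_by_temperature`` is indexed by temperature with one column per
    state (mean fluxes).  Returns 100*(J_T - J_ref)/J_ref; states with a
    zero reference flux are NaN.
    """
    if reference_temperature not in flux_by_temperature.index:
        raise KeyError(f"reference temperature {reference_temperature} "
                       "not in table")
    ref = flux_by_temperature.loc[reference_temperature]
    out = 100.0 * (flux_by_temperature - ref) / ref
    out.loc[:, (ref == 0).to_numpy()] = np.nan
    return out


@dataclass
class ExponentialFit:
    a: float
    b: float
    r2: float


def fit_exponential(temps, fluxes) -> ExponentialFit:
    """Least-squares fit of J = a * exp(b * T) across assay temperatures.

    The simple two-parameter exponential is the monotone Q10-style family
    used to summarise thermal sensitivity of a respiratory state; a low
    R2 signals a plateau or depression at the warm end.
    """
    T = np.asarray(temps, dtype=float)
    J = np.asarray(fluxes, dtype=float)
    if np.unique(T).size < 4:
        raise ValueError("fit_exponential needs >= 4 temperatures")
    if np.any(J <= 0):
        raise ValueError("fluxes must be positive")
    # log-linear initial values, then true nonlinear least squares
    b0, loga0 = np.polyfit(T, np.log(J), 1)
    popt, _ = optimize.curve_fit(lambda x, a, b: a * np.exp(b * x), T, J,
                                 p0=[np.exp(loga0), b0], maxfev=10000)
    resid = J - popt[0] * np.exp(popt[1] * T)
    sst = float(np.sum((J - J.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    return ExponentialFit(a=float(popt[0]), b=float(popt[1]), r2=float(r2))
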