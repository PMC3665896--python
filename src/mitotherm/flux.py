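"""Oxygen flux from chamber traces.

Respiration is the negative time derivative of the chamber oxygen
concentration, scaled to a mass-specific flux:

    J(t) = -dC/dt [nmol mL^-1 s^-1] * V [mL] * 1000 / m [mg]
         -> pmol O2 s^-1 mg^-1

The derivative is a central difference on a moving-average-smoothed
oxygen signal.  One steady-state flux per titration interval is then
extracted as the median over a plateau window at the end of the
interval, after discarding a settling period following the addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnnotatedTrace, EventMark

#: Defaults: traces settle within a couple of minutes of each addition.
SMOOTH_WINDOW_S = 10.0
SETTLE_S = 120.0
PLATEAU_S = 60.0
MIN_PLATEAU_POINTS = 10


@dataclass
class FluxSeries:
    time: np.ndarray
    flux: np.ndarray               # pmol O2 s^-1 mg^-1
    smooth_window_s: float
    fibre_mass: float
    chamber_volume: float


@dataclass
class IntervalFlux:
    label: str
    t_start: float
    t_end: float
    flux: float                    # plateau (median) flux
    sd: float
    n: int


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    # reflect-pad so the edges keep the local slope
    pad = window // 2
    yp = np.pad(y, pad, mode="reflect")
    sm = np.convolve(yp, kernel, mode="same")
    return sm[pad:pad + y.size] if pad else sm


def compute_flux(trace: AnnotatedTrace,
                 smooth_window_s: float = SMOOTH_WINDOW_S) -> FluxSeries:
    """Mass-specific oxygen flux from the trace's oxygen channel."""
    t = np.asarray(trace.time, dtype=float)
    if t.size < 3:
        raise ValueError("compute_flux needs at least 3 samples")
    if smooth_window_s < 0:
        raise ValueError("smooth_window_s must be >= 0")
    o2 = np.asarray(trace.oxygen, dtype=float)
    dt = float(np.median(np.diff(t)))
    window = max(int(round(smooth_window_s / dt)), 1)
    sm = _moving_average(o2, window)
    dcdt = np.gradient(sm, t)
    m = trace.meta
    flux = -dcdt * m.chamber_volume * 1000.0 / m.fibre_mass
    return FluxSeries(time=t, flux=flux, smooth_window_s=smooth_window_s,
                      fibre_mass=m.fibre_mass,
                      chamber_volume=m.chamber_volume)


def steady_state_flux(flux_series: FluxSeries, events: list[EventMark],
                      settle_s: float = SETTLE_S,
                      plateau_s: float = PLATEAU_S,
                      min_plateau_points: int = MIN_PLATEAU_POINTS,
                      ) -> tuple[list[IntervalFlux], list[str]]:
    """One plateau flux per titration interval.

    Each event opens a half-open interval running to the next event (or
    the record end).  The plateau is the median flux over the final
    ``plateau_s`` of the interval after discarding the first ``settle_s``;
    intervals too short for both are skipped with a ``SKIPPED_INTERVAL``
    issue rather than failing the assay.
    """
    t = flux_series.time
    evs = sorted(events, key=lambda e: e.t)
    out: list[IntervalFlux] = []
    issues: list[str] = []
    for i, ev in enumerate(evs):
        t_end = evs[i + 1].t if i + 1 < len(evs) else float(t[-1])
        if t_end - ev.t < settle_s + plateau_s:
            issues.append(f"SKIPPED_INTERVAL:{ev.label}@{ev.t:g}")
            continue
        w0 = max(t_end - plateau_s, ev.t + settle_s)
        mask = (t >= w0) & (t < t_end)
        if int(mask.sum()) < min_plateau_points:
            issues.append(f"SKIPPED_INTERVAL:{ev.label}@{ev.t:g}")
            continue
        vals = flux_series.flux[mask]
        out.append(IntervalFlux(label=ev.label, t_start=float(ev.t),
                                t_end=float(t_end),
                                flux=float(np.median(vals)),
                                sd=float(np.std(vals, ddof=1)),
                                n=int(mask.sum())))
    return out, issues


def background_correct_cco(cco_flux: float,
                           background_by_temperature: dict,
                           temperature: float) -> tuple[float, list[str]]:
    """Subtract TMPD/ascorbate autoxidation from the CCO flux.

    The chemical background is measured per assay temperature in blank
    chambers; the corrected flux is floored at zero with a warning when
    the background exceeds the signal.
    """
    if temperature not in background_by_temperature:
        raise KeyError(f"no background for temperature {temperature}")
    corrected = cco_flux - float(background_by_temperature[temperature])
    flags = []
    if corrected < 0:
        flags.append("BACKGROUND_EXCEEDS_SIGNAL")
        corrected = 0.0
    return corrected, flags
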