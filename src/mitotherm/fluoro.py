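"""Fluorometric quantification: Amplex-red ROS and Magnesium Green ATP.

ROS: superoxide is dismutated to H2O2 (SOD) and detected via the
Amplex-red / horseradish-peroxidase reaction as resorufin, whose
fluorescence rises linearly with cumulative H2O2 (1:1).  A known
resorufin spike before each assay calibrates fluorescence units per
pmol; per-state H2O2 rates are fluorescence slopes divided by that
sensitivity and tissue mass, reported in fmol H2O2 (mg s)^-1 after
subtracting the chemical blank slope.

ATP: Magnesium Green reports free Mg2+, which falls as nucleotides bind
it; ATP binds Mg2+ more strongly than ADP, so ATP synthesis quenches the
signal.  Separate ADP and ATP titrations give linear quench slopes whose
ratio re-calibrates the ADP response into an ATP scale per assay
temperature; all arithmetic uses quench magnitudes |dF| to avoid sign
ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flux import IntervalFlux
from .io import AnnotatedTrace

ROS_CHANNEL = "fluo_ros"
MGG_CHANNEL = "fluo_mgg"


class CalibrationError(ValueError):
    pass


@dataclass
class RosCalibration:
    sensitivity: float           # fluorescence units per pmol resorufin


@dataclass
class MgGCalibration:
    adp_slope: float             # fluorescence units per uM ADP (quench)
    atp_to_adp_ratio: float      # dimensionless, per temperature
    temperature: float
    adp_pulse_signal: float      # units at the 10 uM ADP reference pulse
    adp_r2: float = 1.0
    atp_r2: float = 1.0


def calibrate_ros(trace: AnnotatedTrace, channel: str = ROS_CHANNEL,
                  window_s: float = 20.0, gap_s: float = 5.0
                  ) -> RosCalibration:
    """Sensitivity from the resorufin spike: step height / amount (pmol)."""
    ev = next((e for e in trace.sorted_events() if e.label == "Resorufin"),
              None)
    if ev is None or not math.isfinite(ev.amount) or ev.amount <= 0:
        raise CalibrationError("no resorufin calibration event with amount")
    t = trace.time
    f = np.asarray(trace.channels[channel], dtype=float)
    before = (t >= ev.t - gap_s - window_s) & (t < ev.t - gap_s)
    after = (t >= ev.t + gap_s) & (t < ev.t + gap_s + window_s)
    if before.sum() < 3 or after.sum() < 3:
        raise CalibrationError("too few samples around the resorufin spike")
    # remove the common drift slope so the step height is unbiased
    step = float(np.median(f[after]) - np.median(f[before]))
    drift = np.polyfit(t[before], f[before], 1)[0]
    step -= drift * float(np.median(t[after]) - np.median(t[before]))
    if step <= 0:
        raise CalibrationError("non-positive resorufin step")
    return RosCalibration(sensitivity=step / ev.amount)


def _interval_slope(t, f, iv: IntervalFlux, settle_s: float,
                    plateau_s: float) -> float | None:
    w0 = max(iv.t_end - plateau_s, iv.t_start + settle_s)
    mask = (t >= w0) & (t < iv.t_end)
    if mask.sum() < 5:
        return None
    return float(np.polyfit(t[mask], f[mask], 1)[0])


def ros_rate(trace: AnnotatedTrace, calibration: RosCalibration,
             intervals: list[IntervalFlux], mass: float | None = None,
             background_slope: float = 0.0, channel: str = ROS_CHANNEL,
             settle_s: float = 120.0, plateau_s: float = 60.0
             ) -> tuple[dict[str, float], list[str]]:
    """Per-interval ROS rates in fmol H2O2 (mg s)^-1.

    rate = (dF/dt - blank) / sensitivity / mass, 1:1 resorufin:H2O2.
    Negative corrected rates are floored at zero and flagged.
    """
    if mass is None:
        mass = trace.meta.fibre_mass
    t = trace.time
    f = np.asarray(trace.channels[channel], dtype=float)
    rates: dict[str, float] = {}
    flags: list[str] = []
    for iv in intervals:
        slope = _interval_slope(t, f, iv, settle_s, plateau_s)
        if slope is None:
            flags.append(f"SKIPPED_INTERVAL:{iv.label}")
            continue
        pmol_s = (slope - background_slope) / calibration.sensitivity
        rate = pmol_s / mass * 1000.0      # pmol -> fmol
        if rate < 0:
            flags.append(f"NEGATIVE_RATE:{iv.label}")
            rate = 0.0
        rates[iv.label] = rate
    return rates, flags


def _quench_slope(concentrations, fluorescence) -> tuple[float, float]:
    """|dF|/d[nucleotide] by least squares; returns (slope, r2)."""
    c = np.asarray(concentrations, dtype=float)
    f = np.abs(np.asarray(fluorescence, dtype=float))
    if c.size < 3:
        raise CalibrationError("titration needs >= 3 points")
    slope, intercept = np.polyfit(c, f, 1)
    resid = f - (slope * c + intercept)
    sst = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
    return float(abs(slope)), float(r2)


def calibrate_mgg(adp_titration, atp_titration, temperature: float,
                  r2_min: float = 0.98, adp_pulse_um: float = 10.0
                  ) -> MgGCalibration:
    """Quench slopes from ADP and ATP titrations and their ratio.

    Each titration is a ``(concentrations_uM, quench_fluorescence)`` pair.
    The quench must be linear over the working range (R2 >= ``r2_min``);
    the 10 uM ADP reference pulse signal is stored for re-calibration.
    """
    adp_slope, adp_r2 = _quench_slope(*adp_titration)
    atp_slope, atp_r2 = _quench_slope(*atp_titration)
    if adp_r2 < r2_min or atp_r2 < r2_min:
        raise CalibrationError(
            f"MgG quench not linear (R2 ADP {adp_r2:.3f}, ATP {atp_r2:.3f})")
    if adp_slope <= 0:
        raise CalibrationError("non-positive ADP quench slope")
    return MgGCalibration(adp_slope=adp_slope,
                          atp_to_adp_ratio=atp_slope / adp_slope,
                          temperature=temperature,
                          adp_pulse_signal=adp_slope * adp_pulse_um,
                          adp_r2=adp_r2, atp_r2=atp_r2)


def atp_rate(trace: AnnotatedTrace, calibration: MgGCalibration,
             intervals: list[IntervalFlux], mass: float | None = None,
             channel: str = MGG_CHANNEL, settle_s: float = 60.0,
             plateau_s: float = 120.0) -> tuple[dict[str, float], list[str]]:
    """Per-interval ATP synthesis rates in pmol ATP s^-1 mg^-1.

    The quench slope |dF/dt| over the interval converts to a chamber
    concentration rate via the ADP slope times the temperature-specific
    ATP/ADP quench ratio, then to moles via the chamber volume.
    """
    if calibration.temperature != trace.meta.temperature:
        raise KeyError(
            f"calibration is for {calibration.temperature} degC, trace at "
            f"{trace.meta.temperature} degC")
    if mass is None:
        mass = trace.meta.fibre_mass
    volume = trace.meta.chamber_volume
    t = trace.time
    f = np.asarray(trace.channels[channel], dtype=float)
    rates: dict[str, float] = {}
    flags: list[str] = []
    denom = calibration.adp_slope * calibration.atp_to_adp_ratio
    for iv in intervals:
        slope = _interval_slope(t, f, iv, settle_s, plateau_s)
        if slope is None:
            flags.append(f"SKIPPED_INTERVAL:{iv.label}")
            continue
        um_per_s = abs(slope) / denom                # uM ATP / s
        pmol_per_s = um_per_s * volume * 1000.0      # chamber total
        rates[iv.label] = pmol_per_s / mass
    return rates, flags


def atp_o_ratio(atp: float, o2_flux: float,
                per_o_atom: bool = False) -> float:
    """ATP synthesis over oxygen consumption in the same state.

    Reported per mole O2 consumed by default; ``per_o_atom`` doubles it
    for the per-oxygen-atom convention.
    """
    if o2_flux <= 0:
        raise ValueError("ATP/O undefined for non-positive oxygen flux")
    ratio = atp / o2_flux
    return 2.0 * ratio if per_o_atom else ratio
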