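"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: oxygraph SUIT
traces (oxygen plus optional ROS / Magnesium Green fluorescence
channels), Doppler heartbeat audio, per-fish heart-rate ramps with a
single break temperature, Michaelis-Menten substrate titrations,
metabolite tables and MgG calibration titrations.  Every generator is a
pure function of its parameters and a seed, and each has a matching
estimator that recovers the generating parameters exactly at zero noise.

Presets (``fig3``, ``exp2_suit``, ``fig8_ros``, ``fig9_kinetics``,
``fig10_atp``) ship as YAML fixture files under ``presets/`` whose true
parameters encode the headline derived statistics of the study the
package emulates; they are data, editable without code changes.

Simulated chamber physics: after each titration the rate relaxes to the
new interval's level as a first-order exponential (default tau = 20 s;
inter-event spacing 300 s, so plateaus are reached well before the next
addition).  Oxygen and fluorescence channels are the integrals of those
rates.  Fish-to-fish variability enters as a multiplicative lognormal
per-interval factor; measurement noise is additive white noise on the
flux (oxygen) or on the fluorescence signal.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import cumulative_trapezoid

from .io import AnnotatedTrace, AssayMeta, EventMark
from .kinetics import TitrationSeries

PRESET_NAMES = ("fig3", "exp2_suit", "fig8_ros", "fig9_kinetics",
                "fig10_atp")

#: ETS is probed by repeated uncoupler steps; the early steps undershoot
#: the maximum, which the max-across-FCCP rule then recovers.
FCCP_STEP_FRACS = (0.85, 0.95, 1.0)

BASELINE_S = 60.0


def load_preset(name: str) -> dict:
    """Load a named preset fixture (or a YAML path) into a dict."""
    if name in PRESET_NAMES:
        text = (resources.files("mitotherm") / "presets" /
                f"{name}.yaml").read_text()
    else:
        with open(name) as fh:
            text = fh.read()
    return yaml.safe_load(text)


# --------------------------------------------------------------------------
# rate-level trace synthesis
# --------------------------------------------------------------------------

def _chained_rate(t, event_times, levels, baseline, tau):
    """Piecewise rate with first-order relaxation chained across events."""
    rate = np.empty(t.size)
    bounds = list(event_times) + [np.inf]
    current = float(baseline)
    mask0 = t < bounds[0]
    rate[mask0] = current
    for i, et in enumerate(event_times):
        mask = (t >= et) & (t < bounds[i + 1])
        level = float(levels[i])
        if tau > 0:
            seg = level + (current - level) * np.exp(-(t[mask] - et) / tau)
            t_next = bounds[i + 1] if np.isfinite(bounds[i + 1]) else t[-1]
            current = level + (current - level) * np.exp(-(t_next - et) / tau)
        else:
            seg = np.full(mask.sum(), level)
            current = level
        rate[mask] = seg
    return rate


def _suit_flux_levels(protocol, states, cco_total, rng, noise_frac):
    """True flux level for the interval opened by each protocol event."""
    levels = []
    n_fccp = 0
    for label in protocol:
        if label == "Mal":
            lvl = 0.8
        elif label == "Pyr":
            lvl = states["LeakI"]
        elif label == "ADP":
            lvl = states["OXPI_pm"]
        elif label == "Glu":
            lvl = states["OXPI"]
        elif label == "Cytc":
            lvl = states["CytC"]
        elif label == "Succ":
            lvl = states["OXPI_II"]
        elif label == "NADH":
            lvl = states["NADH"]
        elif label == "Atr":
            lvl = states["LeakI_II"]
        elif label == "FCCP":
            frac = FCCP_STEP_FRACS[min(n_fccp, len(FCCP_STEP_FRACS) - 1)]
            lvl = states["ETS"] * frac
            n_fccp += 1
        elif label == "Rot":
            lvl = 0.5 * states.get("LeakI_II", 2.0)
        elif label == "Malo":
            lvl = 0.8
        elif label == "Ant":
            lvl = 0.3
        elif label == "TMPD+Asc":
            lvl = cco_total
        else:
            lvl = 0.5
        if noise_frac > 0:
            lvl = lvl * float(np.exp(rng.normal(0.0, noise_frac)))
        levels.append(lvl)
    return levels


_EVENT_AMOUNTS = {
    "Mal": (2.0, "mM"), "Pyr": (10.0, "mM"), "ADP": (2.5, "mM"),
    "Glu": (10.0, "mM"), "Cytc": (10.0, "uM"), "Succ": (10.0, "mM"),
    "NADH": (0.5, "mM"), "Atr": (750.0, "uM"), "FCCP": (0.5, "uM"),
    "Rot": (0.5, "uM"), "Malo": (15.0, "mM"), "Ant": (1.0, "uM"),
    "TMPD+Asc": (0.5, "mM"),
}


def gen_suit_trace(preset: dict, temperature: float, seed: int, *,
                   tau_s: float | None = None,
                   state_noise_frac: float | None = None,
                   sample_noise_sd: float | None = None,
                   subject_id: str = "", group: str = "control"
                   ) -> AnnotatedTrace:
    """One chamber assay trace for a SUIT or ATP preset at one temperature.

    The oxygen channel is piecewise linear with first-order transients
    whose converted segment slopes equal the preset's per-state fluxes;
    fluorescence channels are added when the preset defines ROS or ATP
    ground truth.  Deterministic given (preset, temperature, seed).
    """
    states_key = "o2_states" if "o2_states" in preset else "states"
    if temperature not in preset[states_key]:
        raise KeyError(f"temperature {temperature} not in preset "
                       f"{preset.get('name')}")
    rng = np.random.default_rng(seed)
    tau = preset.get("tau_s", 20.0) if tau_s is None else tau_s
    noise_frac = (preset.get("state_noise_frac", 0.0)
                  if state_noise_frac is None else state_noise_frac)
    samp_sd = (preset.get("sample_noise_sd", 0.0)
               if sample_noise_sd is None else sample_noise_sd)
    dt = preset.get("dt_s", 1.0)
    spacing = preset.get("spacing_s", 300.0)
    mass = preset.get("fibre_mass_mg", 2.0)
    volume = preset.get("chamber_volume_ml", 2.0)
    protocol = list(preset["protocol"])
    states = preset[states_key][temperature]

    events: list[EventMark] = []
    t0 = BASELINE_S
    has_ros = "ros_states" in preset
    has_atp = "atp_states" in preset
    if has_ros:
        events.append(EventMark(t=t0, label="Resorufin",
                                amount=preset.get("resorufin_pmol", 400.0),
                                unit="pmol"))
        t0 += spacing
    if has_atp:
        events.append(EventMark(t=t0, label="ADPpulse",
                                amount=preset.get("adp_pulse_um", 10.0),
                                unit="uM"))
        t0 += spacing
    event_times = [t0 + i * spacing for i in range(len(protocol))]
    for label, et in zip(protocol, event_times):
        amount, unit = _EVENT_AMOUNTS.get(label, (np.nan, ""))
        events.append(EventMark(t=et, label=label, amount=amount, unit=unit))

    t_end = event_times[-1] + spacing
    t = np.arange(0.0, t_end + dt / 2, dt)

    if preset.get("kind") == "atp":
        flux_levels = []
        for label in protocol:
            lvl = {"Mal": 0.8, "Pyr": 0.9 * states["LeakI"],
                   "Glu": states["LeakI"], "ADP": states["OXPI"],
                   "Succ": states["OXPI_II"], "Rot": 2.0, "Malo": 1.0,
                   "Ant": 0.5}.get(label, 0.5)
            if noise_frac > 0:
                lvl = lvl * float(np.exp(rng.normal(0.0, noise_frac)))
            flux_levels.append(lvl)
    else:
        bg = preset.get("cco_background", {}).get(temperature, 0.0)
        # the background is a chamber (not mass-specific) process; it is
        # stored on the flux scale, so add it to the true CCO flux
        flux_levels = _suit_flux_levels(protocol, states,
                                        states.get("CCO", 0.0) + bg,
                                        rng, noise_frac)

    flux = _chained_rate(t, event_times, flux_levels, 0.5, tau)
    if samp_sd > 0:
        flux = flux + rng.normal(0.0, samp_sd, t.size)
    o2_rate = flux * mass / (volume * 1000.0)      # nmol mL^-1 s^-1
    o2 = preset.get("o2_start_nmol_ml", 450.0) - np.concatenate(
        [[0.0], cumulative_trapezoid(o2_rate, t)])
    channels = {"o2_nmol_ml": o2}

    if has_ros:
        sens = preset["ros_sensitivity"]
        bg_slope = preset.get("ros_background_slope", 0.0)
        ros_truth = {s: by_t[temperature]
                     for s, by_t in preset["ros_states"].items()}
        ros_noise = preset.get("ros_noise_frac", 0.0)
        rate_by_label = {"Pyr": "LeakI", "Glu": "OXPI", "Succ": "OXPI_II",
                         "FCCP": "ETS"}
        slopes = []
        for label in protocol:
            state = rate_by_label.get(label)
            if state is None:
                slopes.append(bg_slope)
                continue
            rate = ros_truth[state]
            if ros_noise > 0:
                rate = rate * float(np.exp(rng.normal(0.0, ros_noise)))
            # fmol (mg s)^-1 -> fluorescence units s^-1
            slopes.append(rate * 1e-3 * mass * sens + bg_slope)
        ros_slope = _chained_rate(t, event_times, slopes, bg_slope, tau)
        f = 100.0 + np.concatenate(
            [[0.0], cumulative_trapezoid(ros_slope, t)])
        f = f + sens * preset.get("resorufin_pmol", 400.0) * (
            t >= events[0].t)
        fn = preset.get("fluor_noise_sd", 0.0)
        if fn > 0:
            f = f + rng.normal(0.0, fn, t.size)
        channels["fluo_ros"] = f

    if has_atp:
        adp_slope = preset["adp_slope"][temperature]
        ratio = preset["atp_to_adp_ratio"][temperature]
        atp_truth = preset["atp_states"][temperature]
        by_label = {"ADP": "OXPI", "Succ": "OXPI_II"}
        slopes = []
        for label in protocol:
            state = by_label.get(label)
            if state is None:
                slopes.append(0.0)
                continue
            rate = atp_truth[state]
            if noise_frac > 0:
                rate = rate * float(np.exp(rng.normal(0.0, noise_frac)))
            # pmol s^-1 mg^-1 -> uM s^-1 -> quench units s^-1
            slopes.append(rate * mass / (volume * 1000.0)
                          * adp_slope * ratio)
        q_slope = _chained_rate(t, event_times, slopes, 0.0, tau)
        f = preset.get("mgg_start", 1000.0) - np.concatenate(
            [[0.0], cumulative_trapezoid(q_slope, t)])
        f = f - adp_slope * preset.get("adp_pulse_um", 10.0) * (
            t >= events[0].t)
        fn = preset.get("fluor_noise_sd", 0.0)
        if fn > 0:
            f = f + rng.normal(0.0, fn, t.size)
        channels["fluo_mgg"] = f

    meta = AssayMeta(temperature=temperature, fibre_mass=mass,
                     chamber_volume=volume, subject_id=subject_id,
                     group=group)
    return AnnotatedTrace(time=t, channels=channels, events=events,
                          meta=meta)


# --------------------------------------------------------------------------
# Doppler heartbeat audio
# --------------------------------------------------------------------------

def gen_doppler(rate_bpm: float, duration_s: float, noise_sd: float,
                seed: int, sample_rate: float = 8000.0,
                carrier_hz: float = 200.0, burst_sd_s: float = 0.01
                ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Doppler audio: Gaussian-windowed tone bursts plus noise.

    Returns ``(waveform, beat_times)``; exactly
    ``floor(rate_bpm * duration_s / 60)`` bursts at known times.
    """
    if rate_bpm <= 0:
        raise ValueError("rate_bpm must be > 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    period = 60.0 / rate_bpm
    n_beats = int(np.floor(rate_bpm * duration_s / 60.0))
    beat_times = (np.arange(n_beats) + 0.5) * period
    beat_times = beat_times[beat_times < duration_s - 3 * burst_sd_s]
    x = np.zeros(n)
    for bt in beat_times:
        lo = max(int((bt - 4 * burst_sd_s) * sample_rate), 0)
        hi = min(int((bt + 4 * burst_sd_s) * sample_rate), n)
        tt = t[lo:hi] - bt
        x[lo:hi] += (np.exp(-0.5 * (tt / burst_sd_s) ** 2)
                     * np.sin(2 * np.pi * carrier_hz * tt))
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    return x, beat_times


# --------------------------------------------------------------------------
# cardiac temperature ramps
# --------------------------------------------------------------------------

def gen_cardiac_ramp(preset: dict, seed: int
                     ) -> tuple[pd.DataFrame, dict[int, float]]:
    """Per-fish (temperature, heart-rate) ramps with a single break.

    Each fish follows two connected lines meeting at its own true
    breakpoint (drawn around the preset mean) plus Gaussian rate noise.
    Returns the long-format table and the per-fish true breakpoints.
    """
    n_fish = int(preset["n_fish"])
    if n_fish < 2:
        raise ValueError("n_fish must be >= 2")
    step = float(preset["t_step_c"])
    if step <= 0:
        raise ValueError("t_step_c must be > 0")
    rng = np.random.default_rng(seed)
    temps = np.arange(preset["t_start_c"], preset["t_end_c"] + step / 2,
                      step)
    bp_mean = float(preset["breakpoint_mean_c"])
    bp_sd = float(preset["breakpoint_sd_c"])
    s1 = float(preset["slope_pre_bpm_per_c"])
    s2 = float(preset["slope_post_bpm_per_c"])
    r0 = float(preset["rate_at_start_bpm"])
    noise = float(preset["rate_noise_sd_bpm"])
    rows = []
    truth: dict[int, float] = {}
    for fish in range(n_fish):
        bp = float(np.clip(rng.normal(bp_mean, bp_sd),
                           temps[2] + 0.25, temps[-3] - 0.25))
        truth[fish] = bp
        rate = r0 + s1 * (temps - temps[0])
        post = temps > bp
        rate_bp = r0 + s1 * (bp - temps[0])
        rate[post] = rate_bp + s2 * (temps[post] - bp)
        if noise > 0:
            rate = rate + rng.normal(0.0, noise, temps.size)
        for T, r in zip(temps, rate):
            rows.append((fish, float(T), float(r)))
    df = pd.DataFrame(rows, columns=["fish", "temperature", "rate"])
    return df, truth


# --------------------------------------------------------------------------
# titrations and tables
# --------------------------------------------------------------------------

def gen_titration_series(km: float, vmax: float, concentrations,
                         noise_sd: float, seed: int,
                         substrate: str = "pyruvate",
                         temperature: float = 20.0) -> TitrationSeries:
    """Michaelis-Menten titration: rates = vmax*c/(km+c) plus noise.

    ``noise_sd`` is relative: the additive noise sd at each point is
    ``noise_sd`` times the model rate there.
    """
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be > 0")
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("empty concentration list")
    if np.any(c < 0):
        raise ValueError("negative concentration")
    rng = np.random.default_rng(seed)
    v = vmax * c / (km + c)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd * v)
    return TitrationSeries(concentrations=c, rates=v, substrate=substrate,
                           temperature=temperature)


def gen_metabolite_table(group_means: dict[str, tuple[float, float]],
                         cv: float, n_per_group: int, seed: int,
                         is_cv: float = 0.02) -> pd.DataFrame:
    """Lognormal metabolite abundances per group with an internal standard.

    ``group_means`` maps metabolite to (control mean, experimental mean)
    of the internal-standard-normalized abundance; ``cv`` is the
    coefficient of variation of each lognormal draw.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if any(m <= 0 for pair in group_means.values() for m in pair):
        raise ValueError("means must be > 0")
    rng = np.random.default_rng(seed)

    def lognorm(mean, cv_, size):
        sigma = np.sqrt(np.log1p(cv_ ** 2))
        mu = np.log(mean) - sigma ** 2 / 2
        return rng.lognormal(mu, sigma, size)

    frames = []
    for group, col in (("control", 0), ("experimental", 1)):
        data = {"group": [group] * n_per_group,
                "internal_standard": lognorm(1.0, is_cv, n_per_group)}
        for metab, pair in group_means.items():
            data[metab] = (lognorm(pair[col], cv, n_per_group)
                           * data["internal_standard"])
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def gen_mgg_titrations(adp_slope: float, ratio: float, concentrations,
                       noise_frac: float, seed: int):
    """ADP and ATP quench titrations with known slopes (magnitudes)."""
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    f_adp = adp_slope * c
    f_atp = adp_slope * ratio * c
    if noise_frac > 0:
        f_adp = f_adp * (1 + rng.normal(0.0, noise_frac, c.size))
        f_atp = f_atp * (1 + rng.normal(0.0, noise_frac, c.size))
    return (c, f_adp), (c, f_atp)


def gen_saturation_series(slope: float, intercept: float, x, noise_sd: float,
                          seed: int, group: str = "control",
                          subject_id: str = ""):
    """A 940:600 absorbance-ratio series drifting linearly with noise."""
    from .cardiac import SaturationSeries
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    ratio = intercept + slope * x
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, x.size)
    return SaturationSeries(x=x, ratio=ratio, group=group,
                            subject_id=subject_id)
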