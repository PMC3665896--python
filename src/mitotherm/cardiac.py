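"""Cardiac function: heartbeat detection, break temperature, saturation.

Heartbeats are detected from Doppler audio by a sliding root-mean-square
envelope: every maximal contiguous region where the envelope exceeds a
fraction (default 50%) of its maximum yields one beat at the region's
envelope peak.  The threshold is relative, so detection is invariant to
overall amplitude scaling.

The Arrhenius break temperature (ABT) of heart rate is the breakpoint of
a continuous two-segment regression of per-fish rate against ramp
temperature; fish whose rates fit a single line are flagged as no-break
and excluded from the mean.

Haemoglobin saturation is followed as the 940:600 nm absorbance ratio;
control fish (constant temperature) are regressed on time and heat-ramped
fish on temperature, each with a pointwise 95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from . import stats as mstats
from .stats import SegmentedFit


@dataclass
class BeatSeries:
    beat_times: np.ndarray          # s, strictly increasing
    rate_bpm: float
    envelope: np.ndarray
    flags: list[str] = field(default_factory=list)


@dataclass
class SaturationSeries:
    x: np.ndarray                   # degC (experimental) or minutes (control)
    ratio: np.ndarray               # A940 / A600
    group: str = "control"
    subject_id: str = ""

    @property
    def percent_change(self) -> np.ndarray:
        return 100.0 * (self.ratio / self.ratio[0] - 1.0)


def detect_beats(waveform, sample_rate: float,
                 rms_window_s: float = 0.05,
                 threshold_frac: float = 0.5,
                 merge_gap_s: float = 0.1) -> BeatSeries:
    """Envelope-threshold beat detection.

    The envelope is a sliding RMS over ``rms_window_s``; regions above
    ``threshold_frac`` of its maximum closer than ``merge_gap_s`` merge
    into one beat (fish rates below 300 bpm imply >= 200 ms spacing).
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim == 2:                    # stereo: average the channels
        x = x.mean(axis=1)
    if x.size == 0:
        raise ValueError("empty waveform")
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if rms_window_s <= 0:
        raise ValueError("rms_window_s must be > 0")
    n_win = int(round(rms_window_s * sample_rate))
    if n_win > x.size:
        raise ValueError("RMS window longer than the record")
    n_win = max(n_win, 1)
    # reflect padding: "nearest" would replicate a single edge sample
    # across the window and fabricate beats from one noise spike
    env = np.sqrt(ndimage.uniform_filter1d(x * x, size=n_win,
                                           mode="reflect"))
    duration = x.size / sample_rate
    peak = env.max()
    flags: list[str] = []
    if peak == 0.0:
        return BeatSeries(np.array([]), 0.0, env, flags=["ALL_ZERO"])
    above = env > threshold_frac * peak

    # contiguous regions -> merge gaps shorter than merge_gap_s
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    regions = np.split(idx, splits + 1)
    merged = []
    gap = merge_gap_s * sample_rate
    for r in regions:
        if merged and r[0] - merged[-1][-1] <= gap:
            merged[-1] = np.concatenate([merged[-1], r])
        else:
            merged.append(r)
    beat_idx = np.array([r[np.argmax(env[r])] for r in merged], dtype=int)
    beat_times = beat_idx / sample_rate
    if len(merged) == 1 and merged[0].size == x.size:
        flags.append("DEGENERATE_SINGLE_REGION")
    rate = 60.0 * len(merged) / duration
    return BeatSeries(beat_times=beat_times, rate_bpm=float(rate),
                      envelope=env, flags=flags)


def rate_per_bin(beats: BeatSeries, duration_s: float,
                 bin_s: float = 60.0) -> pd.DataFrame:
    """Heart rate per analysis bin (default one-minute sonogram bins)."""
    edges = np.arange(0.0, duration_s + bin_s, bin_s)
    counts, _ = np.histogram(beats.beat_times, bins=edges)
    widths = np.diff(edges)
    return pd.DataFrame({"t_start": edges[:-1],
                         "rate_bpm": 60.0 * counts / widths})


def abt(rate_by_temperature: pd.DataFrame, per_fish: bool = True,
        grid_step: float = 0.05, n_boot: int = 1000, seed: int = 0
        ) -> dict:
    """Arrhenius break temperature of heart rate.

    ``rate_by_temperature`` needs columns ``fish``, ``temperature`` and
    ``rate``.  Each fish is fitted separately (>= 5 points each); the
    summary reports per-fish breakpoints, their mean +/- SEM and the
    pooled R2.  Single-slope fish carry a no-break flag and are excluded
    from the mean.
    """
    df = rate_by_temperature
    fits: dict = {}
    rng = np.random.default_rng(seed)
    groups = df.groupby("fish") if per_fish else [("all", df)]
    for fish, g in groups:
        x = g["temperature"].to_numpy(dtype=float)
        y = g["rate"].to_numpy(dtype=float)
        if x.size < 5:
            raise ValueError(f"fish {fish}: need >= 5 temperature points")
        fits[fish] = mstats.segmented_fit(
            x, y, grid_step=grid_step, n_boot=n_boot,
            seed=int(rng.integers(0, 2**31 - 1)))
    bps = np.array([f.breakpoint for f in fits.values() if not f.no_break])
    sse = sum(f.sse for f in fits.values())
    sst = sum(np.sum((g["rate"] - g["rate"].mean()) ** 2)
              for _, g in groups) or np.nan
    return {
        "per_fish": fits,
        "breakpoints": bps,
        "mean_breakpoint": float(bps.mean()) if bps.size else float("nan"),
        "sem_breakpoint": (float(bps.std(ddof=1) / np.sqrt(bps.size))
                           if bps.size > 1 else float("nan")),
        "pooled_r2": float(1.0 - sse / sst) if sst else float("nan"),
        "n_no_break": sum(f.no_break for f in fits.values()),
    }


def hb_ratio_trend(series_list: list[SaturationSeries],
                   alpha: float = 0.05) -> dict:
    """Per-group OLS of the 940:600 ratio with 95% confidence bands.

    Points are pooled within each group (control on time, experimental
    on temperature, as collected); the report states whether the two
    groups' mean-prediction bands overlap at every shared abscissa.
    """
    groups: dict[str, list[SaturationSeries]] = {}
    for s in series_list:
        if s.x.size < 3:
            raise ValueError("each series needs >= 3 points")
        groups.setdefault(s.group, []).append(s)
    report: dict = {"groups": {}}
    bands = {}
    for name, members in groups.items():
        x = np.concatenate([m.x for m in members])
        y = np.concatenate([m.ratio for m in members])
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        grid = np.linspace(x.min(), x.max(), 50)
        pred = fit.get_prediction(sm.add_constant(grid))
        ci = pred.conf_int(alpha=alpha)
        bands[name] = (grid, ci[:, 0], ci[:, 1])
        report["groups"][name] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared),
            "slope_ci": tuple(np.asarray(fit.conf_int(alpha=alpha))[1]),
        }
    if len(bands) == 2:
        (g1, lo1, hi1), (g2, lo2, hi2) = bands.values()
        lo = max(g1.min(), g2.min())
        hi = min(g1.max(), g2.max())
        if hi > lo:
            shared = np.linspace(lo, hi, 50)
            a_lo = np.interp(shared, g1, lo1)
            a_hi = np.interp(shared, g1, hi1)
            b_lo = np.interp(shared, g2, lo2)
            b_hi = np.interp(shared, g2, hi2)
            report["bands_overlap"] = bool(
                np.all((a_lo <= b_hi) & (b_lo <= a_hi)))
    return report
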