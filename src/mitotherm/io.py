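"""Shared data model and on-disk formats for oxygraph chamber assays.

The raw unit of every chamber assay is an :class:`AnnotatedTrace`: a
multichannel time series (oxygen concentration, optional fluorescence
channels) together with a stream of titration-event marks and assay
metadata.  Traces and events are stored as plain comma-delimited text
with one header row; assay metadata travels in a small YAML sidecar.

Canonical units throughout: seconds, nmol O2 per mL, mg wet weight of
fibre, mL of chamber volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Registered titration vocabulary: mitochondrial substrates, poisons,
#: inhibitors and fluorometric calibration additions.
EVENT_VOCABULARY = frozenset({
    "Pyr", "Mal", "Glu", "ADP", "Cytc", "Succ", "NADH", "Atr", "FCCP",
    "Rot", "Malo", "Ant", "TMPD+Asc", "Resorufin", "ADPpulse", "MgG",
})

#: Oxygen concentrations below this are flagged: assays are run
#: hyper-oxygenated so diffusion into fibres never limits flux.
O2_FLOOR_NMOL_ML = 280.0

TRACE_TIME_COL = "time_s"
TRACE_O2_COL = "o2_nmol_ml"
FLUO_PREFIX = "fluo_"


class TraceFormatError(ValueError):
    """A trace or events file does not conform to the column schema."""


class TraceValidationError(ValueError):
    """An AnnotatedTrace violates a structural invariant."""


@dataclass
class AssayMeta:
    """Chamber and subject metadata for one assay."""

    temperature: float = 20.0        # assay temperature, degC
    fibre_mass: float = 2.0          # mg wet weight
    chamber_volume: float = 2.0      # mL
    subject_id: str = ""
    group: str = "control"           # control | experimental


@dataclass
class EventMark:
    """One titration addition: time, registered label, amount."""

    t: float
    label: str
    amount: float = math.nan
    unit: str = ""


@dataclass
class AnnotatedTrace:
    time: np.ndarray
    channels: dict[str, np.ndarray]
    events: list[EventMark] = field(default_factory=list)
    meta: AssayMeta = field(default_factory=AssayMeta)

    @property
    def oxygen(self) -> np.ndarray:
        return self.channels[TRACE_O2_COL]

    def sorted_events(self) -> list[EventMark]:
        return sorted(self.events, key=lambda e: e.t)


def validate_trace(trace: AnnotatedTrace) -> list[str]:
    """Check all structural invariants; return machine-readable issue codes.

    Reports, never raises.  An empty list means the trace is valid.
    """
    issues: list[str] = []
    t = np.asarray(trace.time, dtype=float)
    if t.size == 0:
        issues.append("EMPTY_TRACE")
        return issues
    if np.any(~np.isfinite(t)):
        issues.append("NON_FINITE_TIME")
    if np.any(np.diff(t) <= 0):
        issues.append("NON_MONOTONE_TIME")
    for name, ch in trace.channels.items():
        if len(ch) != t.size:
            issues.append(f"CHANNEL_LENGTH_MISMATCH:{name}")
    if TRACE_O2_COL in trace.channels:
        o2 = np.asarray(trace.channels[TRACE_O2_COL], dtype=float)
        if np.any(~np.isfinite(o2)):
            issues.append("MISSING_OXYGEN_VALUES")
        elif np.any(o2 < O2_FLOOR_NMOL_ML):
            issues.append("LOW_OXYGEN")
    for ev in trace.events:
        if ev.label not in EVENT_VOCABULARY:
            issues.append("UNKNOWN_EVENT_LABEL")
        if not (t[0] <= ev.t <= t[-1]):
            issues.append("EVENT_OUT_OF_RANGE")
    m = trace.meta
    if m.fibre_mass <= 0:
        issues.append("NONPOSITIVE_MASS")
    if m.chamber_volume <= 0:
        issues.append("NONPOSITIVE_VOLUME")
    if not (0.0 <= m.temperature <= 45.0):
        issues.append("TEMPERATURE_OUT_OF_RANGE")
    return issues


def read_trace(trace_path, events_path=None, meta_path=None,
               meta: AssayMeta | None = None) -> AnnotatedTrace:
    """Read a trace (and optional events / meta sidecars) from disk.

    Raises :class:`TraceFormatError` on a missing required column and
    :class:`TraceValidationError` on non-monotone time or an event mark
    outside the recorded time span.
    """
    df = pd.read_csv(trace_path)
    for col in (TRACE_TIME_COL, TRACE_O2_COL):
        if col not in df.columns:
            raise TraceFormatError(f"missing required column {col!r} "
                                   f"in {trace_path}")
    time = df[TRACE_TIME_COL].to_numpy(dtype=float)
    channels = {TRACE_O2_COL: df[TRACE_O2_COL].to_numpy(dtype=float)}
    for col in df.columns:
        if col.startswith(FLUO_PREFIX):
            channels[col] = df[col].to_numpy(dtype=float)

    events: list[EventMark] = []
    if events_path is not None:
        edf = pd.read_csv(events_path)
        for col in ("t_s", "label"):
            if col not in edf.columns:
                raise TraceFormatError(f"missing required column {col!r} "
                                       f"in {events_path}")
        for row in edf.itertuples(index=False):
            events.append(EventMark(
                t=float(row.t_s), label=str(row.label),
                amount=float(getattr(row, "amount", math.nan)),
                unit="" if pd.isna(getattr(row, "unit", "")) else str(row.unit),
            ))

    if meta is None:
        meta = AssayMeta()
        if meta_path is not None:
            with open(meta_path) as fh:
                meta = AssayMeta(**yaml.safe_load(fh))

    trace = AnnotatedTrace(time=time, channels=channels,
                           events=events, meta=meta)
    issues = validate_trace(trace)
    fatal = {"NON_MONOTONE_TIME", "EVENT_OUT_OF_RANGE", "MISSING_OXYGEN_VALUES"}
    bad = sorted(set(issues) & fatal)
    if bad:
        raise TraceValidationError(f"invalid trace {trace_path}: {bad}")
    return trace


def write_trace(trace: AnnotatedTrace, trace_path, events_path=None,
                meta_path=None) -> None:
    """Write a trace (and optional events / meta sidecars) to disk.

    Lossless at double precision: ``read_trace(write_trace(x)) == x``.
    NaN channel values are written as empty cells and re-read as missing.
    """
    cols = {TRACE_TIME_COL: trace.time}
    cols[TRACE_O2_COL] = trace.channels[TRACE_O2_COL]
    for name, ch in trace.channels.items():
        if name.startswith(FLUO_PREFIX):
            cols[name] = ch
    pd.DataFrame(cols).to_csv(trace_path, index=False,
                              float_format="%.12g")
    if events_path is not None:
        edf = pd.DataFrame(
            [(e.t, e.label, e.amount, e.unit) for e in trace.events],
            columns=["t_s", "label", "amount", "unit"],
        )
        edf.to_csv(events_path, index=False, float_format="%.12g")
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            yaml.safe_dump(asdict(trace.meta), fh, sort_keys=False)


def intervals_from_events(trace: AnnotatedTrace) -> list[tuple[str, float, float]]:
    """Half-open titration intervals ``[t_event, t_next)``.

    Each event applies from its timestamp until the next event; the final
    event's interval runs to the end of the record.
    """
    evs = trace.sorted_events()
    out = []
    for i, ev in enumerate(evs):
        t_end = evs[i + 1].t if i + 1 < len(evs) else float(trace.time[-1])
        out.append((ev.label, ev.t, t_end))
    return out
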