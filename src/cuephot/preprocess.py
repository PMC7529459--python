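"""Trace conditioning: baseline fit, %dF/F0, session Z-score, decimation.

The baseline F0 is an ordinary least-squares polynomial (order 1, or 2 for
pronounced photobleaching) fit over the whole recording session; the
percent change %dF/F0 = 100*(F - F0)/F0 is then Z-scored over the session
(population SD) to give the Z%dF/F0 used by all downstream analyses. Each
channel is processed fully independently. Acquisition-rate traces are
decimated by non-overlapping block means.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .synth import RawTrace

__all__ = [
    "Channel",
    "ProcessedTrace",
    "PreprocessError",
    "BaselineError",
    "fit_baseline",
    "compute_dff",
    "zscore_trace",
    "decimate",
    "decimate_array",
    "process_trace",
]


class PreprocessError(ValueError):
    pass


class BaselineError(PreprocessError):
    """The fitted baseline is nonpositive somewhere (pathological trace)."""


class Channel(str, enum.Enum):
    SIGNAL = "SIGNAL"
    REFERENCE = "REFERENCE"


@dataclass
class ProcessedTrace:
    """Per-channel conditioned trace with the statistics that produced it."""

    time_s: np.ndarray
    f0_au: np.ndarray
    pct_dff: np.ndarray
    z: np.ndarray
    fit_order: int
    channel: Channel
    stats: tuple[float, float]  # (mean, population SD) of pct_dff used for Z
    fs_hz: float


def fit_baseline(trace_channel: np.ndarray, order: int,
                 time_s: np.ndarray | None = None) -> np.ndarray:
    """OLS polynomial baseline of the given order, evaluated on the grid.

    The fit is time-origin invariant: shifting ``time_s`` by a constant
    yields identical baseline values.
    """
    y = np.asarray(trace_channel, dtype=float)
    if order not in (1, 2):
        raise PreprocessError(f"fit order must be 1 or 2, got {order}")
    if y.size < order + 2:
        raise PreprocessError(f"need at least {order + 2} samples for order {order}")
    if not np.all(np.isfinite(y)):
        raise PreprocessError("non-finite values in trace")
    t = np.arange(y.size, dtype=float) if time_s is None else np.asarray(time_s, float)
    if t.size != y.size:
        raise PreprocessError("time grid length mismatch")
    # Polynomial.fit maps t onto [-1, 1], which keeps the normal equations
    # well conditioned for ~30 min sessions and makes the fit shift-invariant
    f0 = Polynomial.fit(t, y, deg=order)(t)
    if np.any(f0 <= 0):
        raise BaselineError("fitted baseline is nonpositive; trace is pathological")
    return f0


def compute_dff(trace_channel: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """Percent change from baseline: 100 * (F - F0) / F0, pointwise."""
    f = np.asarray(trace_channel, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise BaselineError("F0 must be positive everywhere")
    return 100.0 * (f - f0) / f0


def zscore_trace(pct_dff: np.ndarray) -> np.ndarray:
    """Session Z-score with population SD; errors on a constant input."""
    x = np.asarray(pct_dff, dtype=float)
    sd = float(np.std(x))
    if sd == 0:
        raise PreprocessError("zero-variance trace cannot be Z-scored")
    return (x - np.mean(x)) / sd


def decimate_array(x: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means; trailing partial block is dropped."""
    if factor < 1 or int(factor) != factor:
        raise PreprocessError("decimation factor must be a positive integer")
    x = np.asarray(x, dtype=float)
    if x.size < factor:
        raise PreprocessError("trace shorter than one decimation block")
    n = (x.size // factor) * factor
    return x[:n].reshape(-1, factor).mean(axis=1)


def decimate(raw: RawTrace, factor: int) -> RawTrace:
    """Block-mean decimation of both channels; output rate is fs/factor."""
    factor = int(factor)
    sig = decimate_array(raw.signal_au, factor)
    ref = decimate_array(raw.reference_au, factor)
    fs = raw.fs_hz / factor
    # block means are stamped at the block start, keeping the grid uniform
    t = raw.time_s[0] + np.arange(sig.size) / fs
    return RawTrace(time_s=t, signal_au=sig, reference_au=ref, fs_hz=fs,
                    channel_labels=raw.channel_labels, meta=dict(raw.meta))


def process_trace(raw: RawTrace, order: int = 1,
                  channel: Channel = Channel.SIGNAL) -> ProcessedTrace:
    """Full conditioning chain for one channel of a raw trace."""
    channel = Channel(channel)
    y = raw.signal_au if channel is Channel.SIGNAL else raw.reference_au
    f0 = fit_baseline(y, order, time_s=raw.time_s)
    dff = compute_dff(y, f0)
    z = zscore_trace(dff)
    return ProcessedTrace(
        time_s=raw.time_s,
        f0_au=f0,
        pct_dff=dff,
        z=z,
        fit_order=order,
        channel=channel,
        stats=(float(np.mean(dff)), float(np.std(dff))),
        fs_hz=raw.fs_hz,
    )
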