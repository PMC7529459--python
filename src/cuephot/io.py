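"""Readers and writers for event logs, traces, matrices and results.

CSV is the interchange dialect (times in seconds, millisecond precision,
``#``-prefixed metadata header lines); HDF5 is the bulk store for long
traces. Every writer/reader pair round-trips losslessly at the declared
precision.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .align import WarpedHeatmap
from .behavior import SessionSummary
from .bootstrap import BootstrapResult
from .events import Event, EventCode, EventLog, Phase, validate_event_log
from .synth import RawTrace

__all__ = [
    "ParseError",
    "read_event_log",
    "write_event_log",
    "read_trace_csv",
    "write_trace_csv",
    "read_trace_h5",
    "write_trace_h5",
    "write_bootstrap_csv",
    "write_heatmap",
    "write_summaries_csv",
]

TIME_FMT = "{:.3f}"


class ParseError(ValueError):
    pass


def write_event_log(log: EventLog, path) -> Path:
    """Event log as ``time_s,code`` CSV with commented metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# session_id: {log.session_id}\n")
        fh.write(f"# phase: {log.phase.value}\n")
        fh.write(f"# duration_s: {log.duration_s}\n")
        if log.seed is not None:
            fh.write(f"# seed: {log.seed}\n")
        fh.write("time_s,code\n")
        for e in log.events:
            fh.write(f"{TIME_FMT.format(e.time_s)},{e.code.value}\n")
    return path


def read_event_log(path) -> EventLog:
    """Parse and validate an event-log CSV; rejects unknown codes."""
    path = Path(path)
    meta: dict[str, str] = {}
    events: list[Event] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != "time_s,code":
                    raise ParseError(f"{path}:{lineno}: expected header 'time_s,code'")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: malformed row {line!r}")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad time {parts[0]!r}") from exc
            try:
                code = EventCode(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unknown code {parts[1]!r}") from exc
            events.append(Event(t, code))
    log = EventLog(
        events=events,
        phase=Phase(meta.get("phase", "PRE_TRAINING")),
        duration_s=float(meta.get("duration_s", events[-1].time_s if events else 0.0)),
        session_id=meta.get("session_id", ""),
        seed=int(meta["seed"]) if "seed" in meta else None,
    )
    validate_event_log(log)
    return log


def write_trace_csv(trace: RawTrace, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.time_s, "signal_au": trace.signal_au,
         "reference_au": trace.reference_au}
    )
    with path.open("w") as fh:
        fh.write(f"# fs_hz: {trace.fs_hz}\n")
        df.to_csv(fh, index=False)
    return path


def read_trace_csv(path) -> RawTrace:
    path = Path(path)
    fs = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            fs = float(first.split(":")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if fs is None:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        fs = 1.0 / dt
    return RawTrace(
        time_s=df["time_s"].to_numpy(float),
        signal_au=df["signal_au"].to_numpy(float),
        reference_au=df["reference_au"].to_numpy(float),
        fs_hz=fs,
    )


def write_trace_h5(trace: RawTrace, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        g = f.create_group("trace")
        g.create_dataset("time", data=trace.time_s)
        g.create_dataset("signal", data=trace.signal_au)
        g.create_dataset("reference", data=trace.reference_au)
        g.attrs["fs_hz"] = trace.fs_hz
        seed = trace.meta.get("seed")
        if seed is not None:
            g.attrs["seed"] = seed
    return path


def read_trace_h5(path) -> RawTrace:
    with h5py.File(path, "r") as f:
        g = f["trace"]
        return RawTrace(
            time_s=g["time"][()],
            signal_au=g["signal"][()],
            reference_au=g["reference"][()],
            fs_hz=float(g.attrs["fs_hz"]),
            meta={"seed": int(g.attrs["seed"])} if "seed" in g.attrs else {},
        )


def write_bootstrap_csv(res: BootstrapResult, path) -> Path:
    """``bin_time_s,mean,ci_low,ci_high,sig`` CSV plus a JSON params sidecar."""
    path = Path(path)
    bt = (res.bin_time_s if res.bin_time_s is not None
          else np.arange(res.mean.size, dtype=float))
    pd.DataFrame(
        {"bin_time_s": bt, "mean": res.mean, "ci_low": res.ci_low,
         "ci_high": res.ci_high, "sig": res.sig_mask.astype(int)}
    ).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "n_boot": res.params.n_boot,
        "ci_level": res.params.ci_level,
        "consec_s": res.params.consec_s,
        "level": res.params.level.value,
        "seed": res.params.seed,
        "n_rows": res.n_rows,
    }, indent=2))
    return path


def _runlength(mask_row: np.ndarray) -> list[list[int]]:
    runs, start = [], None
    for i, v in enumerate(mask_row):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, int(mask_row.size)])
    return runs


def write_heatmap(hm: WarpedHeatmap, path) -> Path:
    """Heatmap rows as a CSV matrix plus a JSON layout/milestone sidecar."""
    path = Path(path)
    pd.DataFrame(hm.rows, index=[str(d) for d in hm.day_labels]).to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    lay = hm.segment_layout
    sidecar.write_text(json.dumps({
        "segment_layout": {
            "pre_tone_s": lay.pre_tone_s,
            "tone_np_budget_s": lay.tone_np_budget_s,
            "np_rec_budget_s": lay.np_rec_budget_s,
            "post_rec_s": lay.post_rec_s,
            "boundaries_bins": list(lay.boundaries(hm.fs_hz)),
        },
        "fs_hz": hm.fs_hz,
        "day_labels": [str(d) for d in hm.day_labels],
        "n_trials_per_day": hm.n_trials_per_day,
        "milestone_flags": {k: int(v) for k, v in hm.milestone_flags.items()},
        "missing_rle": [_runlength(r) for r in hm.missing_mask],
    }, indent=2))
    return path


def write_summaries_csv(summaries: list[SessionSummary], path, mouse: str = "m1") -> Path:
    """Tidy per-session behavior table ready for external stats tools."""
    path = Path(path)
    pd.DataFrame(
        [{"mouse": mouse, "day": s.day, "phase": s.phase.value,
          "rewards": s.rewards, "correct": s.correct_np,
          "incorrect": s.incorrect_np, "inactive": s.inactive_np,
          "timeouts": s.timeouts} for s in summaries]
    ).to_csv(path, index=False)
    return path
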