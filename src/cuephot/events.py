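"""Timestamped behavioral event logs.

One :class:`EventLog` holds every coded event of a single operant session
(tones, nose pokes, reward delivery, receptacle entries, timeouts, laser
trains) as an ordered ``(time_s, code)`` stream, mirroring the timestamped
export of operant-chamber control software.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "EventCode",
    "Event",
    "EventLog",
    "EventLogError",
    "validate_event_log",
]

#: tolerance for "same timestamp" pairings (correct poke -> reward, etc.)
SAME_TIME_TOL_S = 1e-3


class Phase(str, enum.Enum):
    """Stage of the cue-reward paradigm a session belongs to."""

    FREE_REWARD = "FREE_REWARD"
    FR1 = "FR1"
    PRE_TRAINING = "PRE_TRAINING"
    TRAINING = "TRAINING"
    EXTINCTION = "EXTINCTION"


class EventCode(str, enum.Enum):
    TONE_ON = "TONE_ON"
    TONE_OFF = "TONE_OFF"
    NP_CORRECT = "NP_CORRECT"
    NP_INCORRECT = "NP_INCORRECT"
    NP_INACTIVE = "NP_INACTIVE"
    REWARD_ON = "REWARD_ON"
    REWARD_OFF = "REWARD_OFF"
    RECEPTACLE_ENTRY = "RECEPTACLE_ENTRY"
    RECEPTACLE_LIGHT_OFF = "RECEPTACLE_LIGHT_OFF"
    TIMEOUT_ON = "TIMEOUT_ON"
    TIMEOUT_OFF = "TIMEOUT_OFF"
    LASER_TRAIN_ON = "LASER_TRAIN_ON"
    LASER_TRAIN_OFF = "LASER_TRAIN_OFF"


class Event(NamedTuple):
    time_s: float
    code: EventCode


class EventLogError(ValueError):
    """An event log violates its structural invariants."""


@dataclass
class EventLog:
    """Ordered, coded event stream of one session.

    Parameters
    ----------
    events
        Time-ordered ``Event`` list. Events sharing a timestamp keep their
        causal insertion order (e.g. ``NP_CORRECT`` before ``REWARD_ON``).
    phase
        Paradigm phase the session was run under.
    duration_s
        Scheduled session length; all event times lie in ``[0, duration_s]``.
    """

    events: list[Event]
    phase: Phase
    duration_s: float
    session_id: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def times(self, code: EventCode) -> np.ndarray:
        """Times (s) of every event with the given code."""
        code = EventCode(code)
        return np.array([e.time_s for e in self.events if e.code is code], dtype=float)

    def counts(self) -> dict[EventCode, int]:
        out = {c: 0 for c in EventCode}
        for e in self.events:
            out[e.code] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "code": [e.code.value for e in self.events],
            }
        )

    def with_events(self, extra: Iterable[Event], **meta) -> "EventLog":
        """New log with ``extra`` merged in (stable time order)."""
        merged = sorted(
            list(self.events) + [Event(t, EventCode(c)) for t, c in extra],
            key=lambda e: e.time_s,
        )
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return EventLog(
            events=merged,
            phase=self.phase,
            duration_s=self.duration_s,
            session_id=self.session_id,
            seed=self.seed,
            meta=new_meta,
        )

    def __len__(self) -> int:
        return len(self.events)


_PAIRS = [
    (EventCode.TONE_ON, EventCode.TONE_OFF),
    (EventCode.TIMEOUT_ON, EventCode.TIMEOUT_OFF),
    (EventCode.LASER_TRAIN_ON, EventCode.LASER_TRAIN_OFF),
    (EventCode.REWARD_ON, EventCode.REWARD_OFF),
]


def validate_event_log(log: EventLog, *, tol_s: float = SAME_TIME_TOL_S) -> None:
    """Raise :class:`EventLogError` if ``log`` violates any invariant.

    Checks: nondecreasing times within ``[0, duration_s]``; ON/OFF codes
    strictly alternate for tone, timeout, laser, and reward pairs; every
    ``REWARD_ON`` is coincident (within ``tol_s``) with an ``NP_CORRECT``;
    every ``TIMEOUT_ON`` (Training only) is coincident with an
    ``NP_INCORRECT``; no rewards in Extinction; tones never start inside an
    active timeout.
    """
    t_prev = 0.0
    for e in log.events:
        if not np.isfinite(e.time_s):
            raise EventLogError(f"non-finite event time {e}")
        if e.time_s < -tol_s or e.time_s > log.duration_s + tol_s:
            raise EventLogError(f"event outside session window: {e}")
        if e.time_s < t_prev - tol_s:
            raise EventLogError(f"event times decrease at {e}")
        t_prev = max(t_prev, e.time_s)

    for on, off in _PAIRS:
        state = False
        for e in log.events:
            if e.code is on:
                if state:
                    raise EventLogError(f"{on.value} repeated without {off.value}")
                state = True
            elif e.code is off:
                if not state:
                    raise EventLogError(f"{off.value} without preceding {on.value}")
                state = False
        if state:
            raise EventLogError(f"unterminated {on.value}")

    np_correct = log.times(EventCode.NP_CORRECT)
    for t in log.times(EventCode.REWARD_ON):
        if log.phase is Phase.EXTINCTION:
            raise EventLogError("REWARD_ON in an Extinction session")
        if np_correct.size == 0 or np.min(np.abs(np_correct - t)) > tol_s:
            raise EventLogError(f"REWARD_ON at {t} without coincident NP_CORRECT")

    if log.phase is Phase.TRAINING:
        np_inc = log.times(EventCode.NP_INCORRECT)
        for t in log.times(EventCode.TIMEOUT_ON):
            if np_inc.size == 0 or np.min(np.abs(np_inc - t)) > tol_s:
                raise EventLogError(f"TIMEOUT_ON at {t} without coincident NP_INCORRECT")
    elif log.times(EventCode.TIMEOUT_ON).size:
        raise EventLogError(f"timeouts outside TRAINING ({log.phase.value})")

    # tone must not start during an active timeout
    to_on = log.times(EventCode.TIMEOUT_ON)
    to_off = log.times(EventCode.TIMEOUT_OFF)
    if to_on.size:  # alternation above guarantees equal, paired lengths
        for t in log.times(EventCode.TONE_ON):
            if np.any((to_on <= t + tol_s) & (t < to_off - tol_s)):
                raise EventLogError(f"TONE_ON at {t} inside a timeout")
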