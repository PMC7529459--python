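"""Optogenetic stimulation scheduling.

Two contingencies are modeled. Contingent: a 2 s, 20 Hz, 25 ms-pulse laser
train is triggered by each correct nose poke (pokes landing inside an
already-running train do not retrigger). Non-contingent (yoked): a fixed
number of trains is queued and each is released only when the animal has
made no nose poke in the preceding refractory window, no tone onset falls
within the upcoming guard window, and the post-reward hold after the most
recent rewarded receptacle entry has elapsed; trains additionally never
overlap a tone, a reward-delivery window, or each other.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np

from .events import Event, EventCode, EventLog

__all__ = [
    "StimMode",
    "StimConfig",
    "StimConfigError",
    "pulse_times",
    "schedule_contingent_stim",
    "schedule_noncontingent_stim",
]

log_ = logging.getLogger(__name__)


class StimMode(str, enum.Enum):
    NONE = "NONE"
    CONTINGENT = "CONTINGENT"
    NONCONTINGENT = "NONCONTINGENT"


class StimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StimConfig:
    """Laser train parameters and non-contingent queue rules."""

    train_duration_s: float = 2.0
    pulse_width_ms: float = 25.0
    pulse_rate_hz: float = 20.0
    mode: StimMode = StimMode.NONE
    nc_response_refractory_s: float = 2.0
    nc_pre_tone_guard_s: float = 2.0
    nc_post_reward_release_s: float = 5.0

    def validate(self) -> None:
        if self.pulse_width_ms / 1000.0 >= 1.0 / self.pulse_rate_hz:
            raise StimConfigError("pulse width must be shorter than the pulse period")
        n = self.train_duration_s * self.pulse_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise StimConfigError("train_duration_s * pulse_rate_hz must be an integer")

    @property
    def pulses_per_train(self) -> int:
        return int(round(self.train_duration_s * self.pulse_rate_hz))


def pulse_times(onset_s: float, cfg: StimConfig) -> np.ndarray:
    """Pulse onset times of one train starting at ``onset_s``."""
    cfg.validate()
    return onset_s + np.arange(cfg.pulses_per_train) / cfg.pulse_rate_hz


def schedule_contingent_stim(log: EventLog, stim: StimConfig) -> EventLog:
    """Attach one laser train per correct nose poke, at the poke timestamp.

    A correct poke arriving while a train is still running is ignored (a
    single laser cannot retrigger); the number of ignored triggers is
    recorded in ``meta['stim_ignored_triggers']``.
    """
    stim.validate()
    if stim.mode is not StimMode.CONTINGENT:
        raise StimConfigError(f"contingent scheduling requires mode CONTINGENT, got {stim.mode}")
    extra: list[tuple[float, EventCode]] = []
    last_off = -math.inf
    ignored = 0
    for t in log.times(EventCode.NP_CORRECT):
        if t < last_off:
            ignored += 1
            continue
        off = min(t + stim.train_duration_s, log.duration_s)
        extra.append((t, EventCode.LASER_TRAIN_ON))
        extra.append((off, EventCode.LASER_TRAIN_OFF))
        last_off = off
    if ignored:
        log_.warning("%d correct-poke triggers ignored during active trains", ignored)
    return log.with_events(
        extra,
        stim=stim,
        stim_trains=len(extra) // 2,
        stim_ignored_triggers=ignored,
    )


def _blocked_intervals(log: EventLog, stim: StimConfig) -> list[tuple[float, float]]:
    """Half-open intervals of forbidden train-start times."""
    d = stim.train_duration_s
    blocks: list[tuple[float, float]] = []
    # no nose poke in the last refractory window before the train starts
    for code in (EventCode.NP_CORRECT, EventCode.NP_INCORRECT, EventCode.NP_INACTIVE):
        for p in log.times(code):
            blocks.append((p, p + stim.nc_response_refractory_s))
    # no tone onset within the guard window ahead, and no overlap with a tone
    tone_on = log.times(EventCode.TONE_ON)
    tone_off = log.times(EventCode.TONE_OFF)
    for i, t0 in enumerate(tone_on):
        t1 = tone_off[i] if i < tone_off.size else log.duration_s
        blocks.append((t0 - max(stim.nc_pre_tone_guard_s, d), t1))
    # no overlap with a reward-delivery window
    r_on = log.times(EventCode.REWARD_ON)
    r_off = log.times(EventCode.REWARD_OFF)
    for i, t0 in enumerate(r_on):
        t1 = r_off[i] if i < r_off.size else t0
        blocks.append((t0 - d, t1))
    # post-reward hold after each rewarded receptacle entry
    if r_on.size:
        for e in log.times(EventCode.RECEPTACLE_ENTRY):
            if np.any(r_on <= e):  # entry after a reward was earned
                blocks.append((e, e + stim.nc_post_reward_release_s))
    return sorted(blocks)


def _first_clear(t: float, blocks: list[tuple[float, float]]) -> float:
    """Earliest time >= t outside every half-open blocked interval."""
    moved = True
    while moved:
        moved = False
        for a, b in blocks:
            if a <= t < b:
                t = b
                moved = True
    return t


def schedule_noncontingent_stim(
    log: EventLog,
    n_trains: int,
    stim: StimConfig,
    rng: np.random.Generator,
    request_times_s: np.ndarray | None = None,
) -> EventLog:
    """Deliver up to ``n_trains`` yoked trains under the queue-release rules.

    Each train is requested at a nominal time (uniform random over the
    session unless ``request_times_s`` is given) and held in queue until the
    first instant satisfying every release rule; trains that cannot start
    before session end are dropped, with the drop count reported in
    ``meta['stim_dropped_trains']``.
    """
    stim.validate()
    if stim.mode is not StimMode.NONCONTINGENT:
        raise StimConfigError(
            f"non-contingent scheduling requires mode NONCONTINGENT, got {stim.mode}"
        )
    if n_trains < 0:
        raise StimConfigError("n_trains must be >= 0")
    if request_times_s is None:
        request_times_s = np.sort(rng.uniform(0.0, log.duration_s, size=n_trains))
    else:
        request_times_s = np.sort(np.asarray(request_times_s, dtype=float))
        if request_times_s.size != n_trains:
            raise StimConfigError("request_times_s must have n_trains entries")

    blocks = _blocked_intervals(log, stim)
    extra: list[tuple[float, EventCode]] = []
    prev_end = 0.0
    delivered = 0
    for rt in request_times_s:
        t = _first_clear(max(rt, prev_end), blocks)
        if t + stim.train_duration_s > log.duration_s:
            continue
        extra.append((t, EventCode.LASER_TRAIN_ON))
        extra.append((t + stim.train_duration_s, EventCode.LASER_TRAIN_OFF))
        prev_end = t + stim.train_duration_s
        delivered += 1
    return log.with_events(
        extra,
        stim=stim,
        stim_trains=delivered,
        stim_requested_trains=int(n_trains),
        stim_dropped_trains=int(n_trains) - delivered,
        stim_request_times_s=request_times_s.tolist(),
    )
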