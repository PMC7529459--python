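"""Discrete-event simulation of the cue-reward operant task.

The task: a tone (up to 10 s) is presented on a variable-interval schedule
(mean 30 s, range 10-50 s). An active-port nose poke during the tone
("correct") triggers 2 s of liquid-reward delivery; the tone co-terminates
with delivery. After the animal retrieves the reward (receptacle entry) a
fresh intertrial interval is drawn. Pokes outside the tone ("incorrect")
have no consequence in Pre-Training; in Training they trigger a 5 s timeout
after which the same intertrial interval restarts in full. In Extinction
correct pokes no longer deliver reward.

The synthetic animal is a two-state Poisson poker (separate tone / ITI
rates) with lognormal retrieval latency.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .events import Event, EventCode, EventLog, Phase

__all__ = [
    "TaskConfig",
    "AgentParams",
    "TaskConfigError",
    "draw_vi_interval",
    "simulate_session",
]


class TaskConfigError(ValueError):
    """Invalid task, agent, or phase configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """Task-contingency parameters (durations in seconds)."""

    session_duration_s: float = 1800.0
    tone_max_s: float = 10.0
    reward_delivery_s: float = 2.0
    reward_volume_ul: float = 24.0  # metadata only
    timeout_s: float = 5.0
    vi_mean_s: float = 30.0
    vi_min_s: float = 10.0
    vi_max_s: float = 50.0
    acquisition_threshold_rewards: int = 20
    phase: Phase = Phase.PRE_TRAINING

    def validate(self) -> None:
        if not (self.vi_min_s <= self.vi_mean_s <= self.vi_max_s):
            raise TaskConfigError(
                f"require vi_min <= vi_mean <= vi_max, got "
                f"{self.vi_min_s}, {self.vi_mean_s}, {self.vi_max_s}"
            )
        for name in ("tone_max_s", "reward_delivery_s", "timeout_s",
                     "vi_min_s", "session_duration_s"):
            if getattr(self, name) <= 0:
                raise TaskConfigError(f"{name} must be > 0")
        if self.acquisition_threshold_rewards < 1:
            raise TaskConfigError("acquisition_threshold_rewards must be >= 1")


@dataclass(frozen=True)
class AgentParams:
    """Parametric synthetic animal.

    ``rate_tone_hz`` may be ``inf`` to model an animal that pokes at tone
    onset (used for deterministic hand-checkable sessions). Retrieval
    latency is lognormal with median ``retrieval_latency_s[0]`` and log-sd
    ``retrieval_latency_s[1]``; a log-sd of 0 gives a fixed latency.
    ``learning_gain`` is the per-session multiplicative growth of the
    tone-poke rate applied by cohort helpers (not within one session).
    ``scripted_incorrect_s`` replaces the Poisson ITI poke process with an
    explicit poke-time script, for deterministic contingency tests.
    """

    rate_tone_hz: float = 0.1
    rate_iti_hz: float = 0.25
    rate_inactive_hz: float = 0.02
    retrieval_latency_s: tuple[float, float] = (1.0, 0.4)
    learning_gain: float = 1.0
    seed: int | None = None
    scripted_incorrect_s: tuple[float, ...] | None = None

    def validate(self) -> None:
        for name in ("rate_tone_hz", "rate_iti_hz", "rate_inactive_hz"):
            v = getattr(self, name)
            if not v >= 0 or math.isnan(v):
                raise TaskConfigError(f"{name} must be >= 0")
        loc, scale = self.retrieval_latency_s
        if not (loc > 0 and scale >= 0):
            raise TaskConfigError("retrieval latency needs median > 0 and log-sd >= 0")

    def after_sessions(self, n: int) -> "AgentParams":
        """Agent after ``n`` sessions of learning (tone rate scaled by gain**n)."""
        return replace(self, rate_tone_hz=self.rate_tone_hz * self.learning_gain ** n)


def draw_vi_interval(config: TaskConfig, rng: np.random.Generator) -> float:
    """One intertrial interval (s), uniform on [vi_min_s, vi_max_s].

    The schedule is specified by its mean and range; a continuous uniform
    draw over the range reproduces the stated mean when it is the midpoint.
    """
    config.validate()
    if config.vi_min_s == config.vi_max_s:
        return float(config.vi_min_s)
    return float(rng.uniform(config.vi_min_s, config.vi_max_s))


def _gap(rng: np.random.Generator, rate_hz: float) -> float:
    """Next exponential inter-event gap; 0 for an infinite rate, inf for 0."""
    if rate_hz == 0:
        return math.inf
    if math.isinf(rate_hz):
        return 0.0
    return float(rng.exponential(1.0 / rate_hz))


def _retrieval_latency(rng: np.random.Generator, agent: AgentParams) -> float:
    loc, scale = agent.retrieval_latency_s
    if scale == 0:
        return float(loc)
    return float(loc * math.exp(scale * rng.standard_normal()))


class _ItiPoker:
    """Source of incorrect-poke times: Poisson stream or explicit script."""

    def __init__(self, rng, agent: AgentParams):
        self._rng = rng
        self._rate = agent.rate_iti_hz
        self._script = (
            sorted(agent.scripted_incorrect_s)
            if agent.scripted_incorrect_s is not None
            else None
        )

    def next_after(self, t: float) -> float:
        if self._script is not None:
            while self._script and self._script[0] <= t:
                self._script.pop(0)
            return self._script[0] if self._script else math.inf
        return t + _gap(self._rng, self._rate)


def simulate_session(
    task: TaskConfig,
    agent: AgentParams,
    stim=None,
    rng: np.random.Generator | None = None,
    session_id: str = "",
) -> EventLog:
    """Simulate one session and return its validated event stream.

    Contingency summary per phase: in PRE_TRAINING incorrect pokes have no
    scheduled consequence; in TRAINING each incorrect poke outside an active
    timeout emits a 5 s timeout and re-arms the full current intertrial
    interval at timeout offset; in EXTINCTION correct pokes emit no reward.
    The tone ends at ``min(onset + tone_max_s, poke + reward_delivery_s)``.
    After retrieval (receptacle entry) a fresh interval is drawn; after an
    unanswered tone the fresh interval counts down from tone offset.

    If ``stim`` is a contingent :class:`~cuephot.stim.StimConfig`, laser
    trains are scheduled onto the returned log.
    """
    task.validate()
    agent.validate()
    if task.phase not in (Phase.PRE_TRAINING, Phase.TRAINING, Phase.EXTINCTION):
        raise TaskConfigError(f"cannot simulate phase {task.phase}")
    if task.session_duration_s <= 0:
        raise TaskConfigError("zero-length session would produce an empty log")
    if rng is None:
        rng = np.random.default_rng(agent.seed)

    T = task.session_duration_s
    ev: list[Event] = []
    vi_draws: list[float] = []

    # inactive-port pokes: independent homogeneous Poisson, locomotor control
    t = 0.0
    while True:
        g = _gap(rng, agent.rate_inactive_hz)
        if not math.isfinite(g):
            break
        t += g
        if t >= T:
            break
        ev.append(Event(t, EventCode.NP_INACTIVE))

    poker = _ItiPoker(rng, agent)
    training = task.phase is Phase.TRAINING
    extinction = task.phase is Phase.EXTINCTION

    iti = draw_vi_interval(task, rng)
    vi_draws.append(iti)
    cursor = 0.0          # start of the current ITI exposure window
    tone_at = cursor + iti

    while tone_at < T:
        # --- intertrial interval: incorrect pokes ---
        tp = poker.next_after(cursor)
        while tp < min(tone_at, T):
            ev.append(Event(tp, EventCode.NP_INCORRECT))
            if training:
                to_end = min(tp + task.timeout_s, T)
                ev.append(Event(tp, EventCode.TIMEOUT_ON))
                ev.append(Event(to_end, EventCode.TIMEOUT_OFF))
                # pokes during the timeout are logged but trigger nothing
                q = poker.next_after(tp)
                while q < to_end:
                    ev.append(Event(q, EventCode.NP_INCORRECT))
                    q = poker.next_after(q)
                cursor = to_end
                tone_at = to_end + iti  # full re-arm of the same interval
            else:
                cursor = tp
            tp = poker.next_after(cursor)
        if tone_at >= T:
            break

        # --- tone ---
        ev.append(Event(tone_at, EventCode.TONE_ON))
        forced_off = min(tone_at + task.tone_max_s, T)
        first_np = tone_at + _gap(rng, agent.rate_tone_hz)
        if first_np < forced_off:
            tone_off = min(tone_at + task.tone_max_s, first_np + task.reward_delivery_s, T)
            p = first_np
            while p < tone_off:
                ev.append(Event(p, EventCode.NP_CORRECT))
                g = _gap(rng, agent.rate_tone_hz)
                if not g > 0:
                    break  # infinite-rate agent: single poke at onset
                p += g
            ev.append(Event(tone_off, EventCode.TONE_OFF))
            if not extinction:
                ev.append(Event(first_np, EventCode.REWARD_ON))
                ev.append(Event(min(first_np + task.reward_delivery_s, T),
                                EventCode.REWARD_OFF))
                rec = first_np + _retrieval_latency(rng, agent)
                if rec >= T:
                    break  # session ends before retrieval
                ev.append(Event(rec, EventCode.RECEPTACLE_ENTRY))
                ev.append(Event(rec, EventCode.RECEPTACLE_LIGHT_OFF))
                iti = draw_vi_interval(task, rng)
                vi_draws.append(iti)
                tone_at = rec + iti          # ITI clock starts at retrieval
                cursor = max(rec, tone_off)  # no active pokes while retrieving
            else:
                iti = draw_vi_interval(task, rng)
                vi_draws.append(iti)
                tone_at = tone_off + iti
                cursor = tone_off
        else:
            ev.append(Event(forced_off, EventCode.TONE_OFF))
            if forced_off >= T:
                break
            iti = draw_vi_interval(task, rng)
            vi_draws.append(iti)
            tone_at = forced_off + iti
            cursor = forced_off

    ev.sort(key=lambda e: e.time_s)  # stable: ties keep causal order
    log = EventLog(
        events=ev,
        phase=task.phase,
        duration_s=T,
        session_id=session_id,
        seed=agent.seed,
        meta={"vi_draws_s": vi_draws, "task": task, "agent": agent},
    )
    if stim is not None:
        from .stim import StimMode, schedule_contingent_stim

        if stim.mode is StimMode.CONTINGENT:
            log = schedule_contingent_stim(log, stim)
    return log
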