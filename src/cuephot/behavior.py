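"""Session summaries, acquisition detection, and design power analysis."""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .events import EventCode, EventLog, Phase

__all__ = [
    "SessionSummary",
    "PowerSpec",
    "BehaviorError",
    "summarize_session",
    "detect_acquisition",
    "sample_size_two_groups",
]


class BehaviorError(ValueError):
    pass


@dataclass(frozen=True)
class SessionSummary:
    day: int
    phase: Phase
    rewards: int
    correct_np: int
    incorrect_np: int
    inactive_np: int
    timeouts: int


def summarize_session(log: EventLog, day: int = 0) -> SessionSummary:
    """Event counts of one session; rewards are counted at delivery onset."""
    c = log.counts()
    return SessionSummary(
        day=day,
        phase=log.phase,
        rewards=c[EventCode.REWARD_ON],
        correct_np=c[EventCode.NP_CORRECT],
        incorrect_np=c[EventCode.NP_INCORRECT],
        inactive_np=c[EventCode.NP_INACTIVE],
        timeouts=c[EventCode.TIMEOUT_ON],
    )


def detect_acquisition(summaries: list[SessionSummary],
                       threshold: int = 20) -> int | None:
    """First Training day from which rewards stay at or above ``threshold``.

    "Consistently earning 20 rewards" is formalized as a suffix rule: the
    acquisition day is the first Training day whose rewards and those of
    every later Training day reach the threshold; ``None`` if never.
    """
    tr = [s for s in summaries if s.phase is Phase.TRAINING]
    acq = None
    for s in tr:
        if s.rewards >= threshold:
            if acq is None:
                acq = s.day
        else:
            acq = None
    return acq


@dataclass(frozen=True)
class PowerSpec:
    """Two-independent-sample design under a normal approximation."""

    mean_a: float
    mean_b: float
    sd: float
    alpha: float = 0.05
    power: float = 0.90

    def validate(self) -> None:
        if self.sd <= 0:
            raise BehaviorError("sd must be > 0")
        if not 0 < self.alpha < 1:
            raise BehaviorError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise BehaviorError("power must be in (0, 1)")
        if self.mean_a == self.mean_b:
            raise BehaviorError("zero effect size: required n diverges")


def sample_size_two_groups(spec: PowerSpec) -> int:
    """Per-group n for a two-sided two-sample comparison of means.

    n = ceil( 2*sd^2 * (z_{1-alpha/2} + z_{power})^2 / (mean_a - mean_b)^2 ),
    floored at 2 per group.
    """
    spec.validate()
    z_a = norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = norm.ppf(spec.power)
    n = 2.0 * spec.sd**2 * (z_a + z_b) ** 2 / (spec.mean_a - spec.mean_b) ** 2
    return max(2, math.ceil(n))
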