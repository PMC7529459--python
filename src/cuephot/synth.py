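"""Synthetic two-channel fluorescence traces locked to an event log.

The signal channel is a positive baseline carrying polynomial photobleaching
drift, multiplicative event-locked transients (difference-of-exponentials
kernel), a shared motion artifact, and Gaussian noise. The reference channel
carries the same baseline, drift, and motion but no transients, emulating a
near-isosbestic control wavelength.

Transient amplitudes are organized as per-learning-stage schedules: which
task event drives the dominant fluorescence peak migrates across learning
(nose-poke-locked early, retrieval-locked in early training, tone-locked
after acquisition), and separate schedules emulate principal-cell calcium
dynamics (retrieval-locked until acquisition, then tone-locked).
"""
from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .events import EventCode, EventLog

__all__ = [
    "LearningStage",
    "PhotoParams",
    "RawTrace",
    "SynthError",
    "transient_kernel",
    "kernel_time_to_peak",
    "stage_schedule_presets",
    "synthesize_trace",
]


class SynthError(ValueError):
    pass


class LearningStage(str, enum.Enum):
    """Which event dominates the event-locked fluorescence response."""

    PRETRAIN = "PRETRAIN"                  # nose-poke-locked
    EARLY_TRAIN = "EARLY_TRAIN"            # retrieval-locked
    ACQUIRED = "ACQUIRED"                  # tone-locked
    EXTINCTION = "EXTINCTION"              # tone-locked, decaying
    CAMKII_PRETRAIN = "CAMKII_PRETRAIN"    # retrieval-locked
    CAMKII_EARLY_TRAIN = "CAMKII_EARLY_TRAIN"
    CAMKII_ACQUIRED = "CAMKII_ACQUIRED"    # tone-locked
    CAMKII_EXTINCTION = "CAMKII_EXTINCTION"


# schedule: event code -> tuple of (fractional amplitude, onset delay s)
Schedule = dict[EventCode, tuple[tuple[float, float], ...]]


def stage_schedule_presets() -> dict[LearningStage, Schedule]:
    """Per-stage transient amplitude schedules (fraction of baseline).

    Amplitudes encode the observed migration of the event-locked peak:
    Pre-Training shows the largest response at the correct nose poke with a
    smaller retrieval peak and a delayed post-poke dip; early Training is
    retrieval-dominated; after acquisition the tone response dominates and
    the poke response shrinks; Extinction keeps a weakened tone response.
    Incorrect pokes always evoke a smaller response than correct pokes.
    CAMKII variants are retrieval-locked until acquisition, then tone-locked,
    with a small negative deflection after incorrect pokes.
    """
    c, i, r, t = (EventCode.NP_CORRECT, EventCode.NP_INCORRECT,
                  EventCode.RECEPTACLE_ENTRY, EventCode.TONE_ON)
    return {
        LearningStage.PRETRAIN: {
            c: ((0.05, 0.0), (-0.02, 2.5)),
            r: ((0.012, 0.0),),
            i: ((0.01, 0.0),),
        },
        LearningStage.EARLY_TRAIN: {
            r: ((0.05, 0.0),),
            c: ((0.02, 0.0),),
            t: ((0.005, 0.0),),
            i: ((0.01, 0.0),),
        },
        LearningStage.ACQUIRED: {
            t: ((0.05, 0.0),),
            c: ((0.015, 0.0),),
            r: ((0.015, 0.0),),
            i: ((0.005, 0.0),),
        },
        LearningStage.EXTINCTION: {
            t: ((0.02, 0.0),),
            c: ((0.01, 0.0),),
            i: ((0.005, 0.0),),
        },
        LearningStage.CAMKII_PRETRAIN: {
            r: ((0.05, 0.0),),
            c: ((0.015, 0.0),),
            i: ((-0.01, 0.0),),
        },
        LearningStage.CAMKII_EARLY_TRAIN: {
            r: ((0.05, 0.0),),
            c: ((0.015, 0.0),),
            i: ((-0.01, 0.0),),
        },
        LearningStage.CAMKII_ACQUIRED: {
            t: ((0.05, 0.0),),
            r: ((0.03, 0.0),),
            c: ((0.015, 0.0),),
            i: ((-0.005, 0.0),),
        },
        LearningStage.CAMKII_EXTINCTION: {
            t: ((0.02, 0.0),),
            c: ((0.01, 0.0),),
            i: ((-0.005, 0.0),),
        },
    }


@dataclass(frozen=True)
class PhotoParams:
    """Synthetic-photometry generator parameters.

    ``bleach_coeffs`` are fractional drift polynomial coefficients over the
    session: drift(t) = c1*(t/T) + c2*(t/T)**2; (-0.1,) is a 10% linear
    fade. ``amplitude_schedule`` maps learning stage to an event schedule;
    defaults to :func:`stage_schedule_presets`.
    """

    fs_hz: float = 120.0
    baseline_au: float = 100.0
    bleach_coeffs: tuple[float, ...] = (-0.1,)
    #: optional exponential bleaching (fractional_fade, tau_s); unlike the
    #: polynomial drift this is NOT removed exactly by the baseline fit,
    #: exercising model mismatch
    exp_bleach: tuple[float, float] | None = None
    noise_sd_au: float = 1.0
    motion_sd_au: float = 0.0
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.0
    amplitude_schedule: dict | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise SynthError("fs_hz must be > 0")
        if not 0 < self.kernel_rise_s < self.kernel_decay_s:
            raise SynthError("require 0 < kernel_rise_s < kernel_decay_s")
        if self.baseline_au <= 0:
            raise SynthError("baseline_au must be > 0")
        if len(self.bleach_coeffs) not in (0, 1, 2):
            raise SynthError("bleach_coeffs supports order 1 or 2 drift")

    def schedule_for(self, stage: LearningStage) -> Schedule:
        sched = self.amplitude_schedule or stage_schedule_presets()
        stage = LearningStage(stage)
        if stage not in sched:
            raise SynthError(f"no amplitude schedule for stage {stage}")
        out: Schedule = {}
        for code, comps in sched[stage].items():
            try:
                key = EventCode(code)
            except ValueError as exc:
                raise SynthError(f"schedule references unknown event type {code!r}") from exc
            if isinstance(comps, (int, float)):
                comps = ((float(comps), 0.0),)
            out[key] = tuple((float(a), float(d)) for a, d in comps)
        return out


@dataclass
class RawTrace:
    """Uniformly sampled two-channel fluorescence recording."""

    time_s: np.ndarray
    signal_au: np.ndarray
    reference_au: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, str] = ("signal", "reference")
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        n = self.time_s.size
        if self.signal_au.size != n or self.reference_au.size != n:
            raise SynthError("channel lengths differ from the time grid")
        if n > 1:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-6, atol=1e-9):
                raise SynthError("time grid is not uniform at fs_hz")
        if np.any(self.signal_au <= 0) or np.any(self.reference_au <= 0):
            raise SynthError("fluorescence values must be positive")


def transient_kernel(t, rise: float, decay: float) -> np.ndarray:
    """Causal difference-of-exponentials kernel, peak-normalized to 1."""
    if not 0 < rise < decay:
        raise SynthError("require 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    tp = kernel_time_to_peak(rise, decay)
    peak = math.exp(-tp / decay) - math.exp(-tp / rise)
    return k / peak


def kernel_time_to_peak(rise: float, decay: float) -> float:
    """Closed-form argmax of the difference-of-exponentials kernel."""
    return rise * decay / (decay - rise) * math.log(decay / rise)


def synthesize_trace(
    log: EventLog,
    p: PhotoParams,
    stage: LearningStage,
    rng: np.random.Generator | None = None,
) -> RawTrace:
    """Generate a two-channel trace locked to ``log`` under stage ``stage``.

    signal = baseline * (1 + drift) * (1 + sum of event transients)
             + motion + noise;
    reference = baseline * (1 + drift) + motion + independent noise.
    Values are clipped to a small positive floor with a warning if the
    requested drift/noise would drive them nonpositive.
    """
    p.validate()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    sched = p.schedule_for(stage)

    n = int(round(log.duration_s * p.fs_hz))
    t = np.arange(n) / p.fs_hz
    frac = t / log.duration_s
    drift = np.zeros(n)
    for k, c in enumerate(p.bleach_coeffs, start=1):
        drift += c * frac**k
    if p.exp_bleach is not None:
        fade, tau = p.exp_bleach
        drift += -fade * (1.0 - np.exp(-t / tau))

    impulses = np.zeros(n)
    for code, comps in sched.items():
        for amp, delay in comps:
            for te in log.times(code):
                i = int(round((te + delay) * p.fs_hz))
                if 0 <= i < n:
                    impulses[i] += amp
    if impulses.any():
        tk = np.arange(0.0, 8.0 * p.kernel_decay_s, 1.0 / p.fs_hz)
        kern = transient_kernel(tk, p.kernel_rise_s, p.kernel_decay_s)
        transients = fftconvolve(impulses, kern)[:n]
    else:
        transients = np.zeros(n)

    motion = rng.normal(0.0, p.motion_sd_au, n) if p.motion_sd_au > 0 else 0.0
    noise_sig = rng.normal(0.0, p.noise_sd_au, n) if p.noise_sd_au > 0 else 0.0
    noise_ref = rng.normal(0.0, p.noise_sd_au, n) if p.noise_sd_au > 0 else 0.0
    signal = p.baseline_au * (1.0 + drift) * (1.0 + transients) + motion + noise_sig
    reference = p.baseline_au * (1.0 + drift) + motion + noise_ref

    floor = 1e-6 * p.baseline_au
    if np.any(signal <= 0) or np.any(reference <= 0):
        warnings.warn("synthesized fluorescence clipped at positive floor", stacklevel=2)
        signal = np.maximum(signal, floor)
        reference = np.maximum(reference, floor)

    return RawTrace(
        time_s=t,
        signal_au=signal,
        reference_au=reference,
        fs_hz=p.fs_hz,
        meta={"stage": LearningStage(stage).value, "seed": p.seed, "params": p},
    )
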