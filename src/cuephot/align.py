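"""Peri-event extraction and three-anchor time-warped heatmaps.

Fixed-window analysis takes each event's Z%dF/F0 from 5 s before to 10 s
after the event (at least 3 trials required). Heatmap rows instead align
every rewarded trial to three anchors - tone onset, correct nose poke, and
receptacle entry - by evenly splitting each trial's variable-latency
segments into fixed 4 s (tone-to-poke) and 1 s (poke-to-retrieval) budgets:
half of a trial's samples are laid forward from the earlier anchor and half
backward from the later anchor, leaving explicitly-missing center bins when
the latency is shorter than the budget (the blank bins of the heatmaps).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import SessionSummary, detect_acquisition
from .events import EventCode, EventLog, Phase
from .preprocess import ProcessedTrace

__all__ = [
    "Trial",
    "PeriEventMatrix",
    "SegmentLayout",
    "WarpedHeatmap",
    "AlignmentError",
    "filter_rewarded_trials",
    "filter_incorrect_events",
    "extract_peri_event",
    "warp_trial",
    "build_daily_heatmap",
    "select_key_days",
]

DEFAULT_WINDOW = (-5.0, 10.0)
MIN_TRIALS = 3


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Trial:
    """Anchors of one rewarded trial (seconds)."""

    tone_t: float
    np_t: float
    rec_t: float

    def __post_init__(self):
        if not self.tone_t <= self.np_t <= self.rec_t:
            raise AlignmentError(f"anchors out of order: {self}")


@dataclass
class PeriEventMatrix:
    """Trials x time-bins matrix of Z%dF/F0 (NaN marks missing bins)."""

    values: np.ndarray
    bin_time_s: np.ndarray
    event_times_s: np.ndarray
    anchor: EventCode
    fs_hz: float
    session_day: int | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


def filter_rewarded_trials(log: EventLog, max_retrieval_s: float = 5.0) -> list[Trial]:
    """Rewarded trials whose receptacle entry came within ``max_retrieval_s``
    of the correct nose poke; each is returned as (tone, poke, entry) anchors.
    """
    tones = log.times(EventCode.TONE_ON)
    recs = log.times(EventCode.RECEPTACLE_ENTRY)
    trials: list[Trial] = []
    for r in log.times(EventCode.REWARD_ON):
        np_t = r  # reward is emitted at the triggering poke's timestamp
        prev_tones = tones[tones <= np_t + 1e-9]
        later_recs = recs[recs >= np_t]
        if prev_tones.size == 0 or later_recs.size == 0:
            continue
        rec_t = float(later_recs[0])
        if rec_t - np_t <= max_retrieval_s:
            trials.append(Trial(float(prev_tones[-1]), float(np_t), rec_t))
    return trials


def filter_incorrect_events(log: EventLog, refractory_s: float = 5.0) -> np.ndarray:
    """Incorrect-poke times not preceded by another incorrect poke within
    ``refractory_s`` (the preceding poke need not itself have been kept)."""
    times = log.times(EventCode.NP_INCORRECT)
    if times.size == 0:
        return times
    keep = np.ones(times.size, dtype=bool)
    keep[1:] = np.diff(times) >= refractory_s
    return times[keep]


def extract_peri_event(
    z: ProcessedTrace,
    event_times: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_trials: int = MIN_TRIALS,
) -> PeriEventMatrix | None:
    """Fixed-window trials x bins matrix around each event.

    Bins follow the half-open convention [window[0], window[1]); bin ``i``
    sits at offset ``window[0] + i/fs``. Events whose window overlaps a
    session edge are dropped with a warning. Returns ``None`` (nothing to
    analyze) when fewer than ``min_trials`` events survive.
    """
    w0, w1 = window
    if not w1 > w0:
        raise AlignmentError("window must have positive length")
    fs = z.fs_hz
    n_bins = int(round((w1 - w0) * fs))
    t0 = float(z.time_s[0])
    rows, kept = [], []
    dropped = 0
    for te in np.asarray(event_times, dtype=float):
        start = int(round((te + w0 - t0) * fs))
        if start < 0 or start + n_bins > z.z.size:
            dropped += 1
            continue
        rows.append(z.z[start:start + n_bins])
        kept.append(te)
    if dropped:
        warnings.warn(f"{dropped} trial(s) dropped at session edges", stacklevel=2)
    if len(rows) < min_trials:
        return None
    return PeriEventMatrix(
        values=np.array(rows, dtype=float),
        bin_time_s=w0 + np.arange(n_bins) / fs,
        event_times_s=np.array(kept, dtype=float),
        anchor=EventCode.NP_CORRECT,
        fs_hz=fs,
    )


@dataclass(frozen=True)
class SegmentLayout:
    """Fixed column budget of the three-anchor composite row."""

    pre_tone_s: float = 5.0
    tone_np_budget_s: float = 4.0
    np_rec_budget_s: float = 1.0
    post_rec_s: float = 5.0

    def bin_counts(self, fs: float) -> tuple[int, int, int, int]:
        return (int(round(self.pre_tone_s * fs)),
                int(round(self.tone_np_budget_s * fs)),
                int(round(self.np_rec_budget_s * fs)),
                int(round(self.post_rec_s * fs)))

    def boundaries(self, fs: float) -> tuple[int, ...]:
        """Cumulative segment edges in columns (pure function of layout/fs)."""
        c = self.bin_counts(fs)
        return (0, c[0], c[0] + c[1], c[0] + c[1] + c[2], sum(c))

    def n_bins(self, fs: float) -> int:
        return sum(self.bin_counts(fs))


def _split_fill(seg: np.ndarray, n_bins: int) -> np.ndarray:
    """Dual-anchor even split of ``seg`` into a fixed ``n_bins`` window.

    Half the samples (extra one to the leading anchor) are placed forward
    from the segment start, half backward from the end; the center stays
    NaN when the trial is shorter than the budget, and over-budget trials
    are center-cropped symmetrically.
    """
    out = np.full(n_bins, np.nan)
    m = seg.size
    if m >= n_bins:
        lead = math.ceil(n_bins / 2)
        trail = n_bins - lead
        out[:lead] = seg[:lead]
        if trail:
            out[n_bins - trail:] = seg[m - trail:]
    else:
        lead = math.ceil(m / 2)
        trail = m - lead
        out[:lead] = seg[:lead]
        if trail:
            out[n_bins - trail:] = seg[lead:]
    return out


def warp_trial(z: ProcessedTrace, tone_t: float, np_t: float, rec_t: float,
               layout: SegmentLayout = SegmentLayout()) -> np.ndarray:
    """Composite row for one rewarded trial (NaN marks missing bins).

    Pre-tone and post-retrieval segments are copied verbatim; the
    tone-to-poke and poke-to-retrieval segments are dual-anchor split into
    their fixed budgets. Returns ``None``-like behavior is not used: trials
    overlapping the trace edge raise, callers should pre-filter.
    """
    if not tone_t <= np_t <= rec_t:
        raise AlignmentError("anchors out of order")
    fs = z.fs_hz
    t0 = float(z.time_s[0])
    n_pre, n_t2n, n_n2r, n_post = layout.bin_counts(fs)
    i_tone = int(round((tone_t - t0) * fs))
    i_np = int(round((np_t - t0) * fs))
    i_rec = int(round((rec_t - t0) * fs))
    if i_tone - n_pre < 0 or i_rec + n_post > z.z.size:
        raise AlignmentError("trial window overlaps the session edge")
    pre = z.z[i_tone - n_pre:i_tone]
    t2n = _split_fill(z.z[i_tone:i_np], n_t2n)
    n2r = _split_fill(z.z[i_np:i_rec], n_n2r)
    post = z.z[i_rec:i_rec + n_post]
    return np.concatenate([pre, t2n, n2r, post])


@dataclass
class WarpedHeatmap:
    """Per-day mean composite rows with explicit missing-bin semantics."""

    rows: np.ndarray                 # days x bins, NaN where missing
    missing_mask: np.ndarray         # True where no trial contributed
    day_labels: list
    segment_layout: SegmentLayout
    fs_hz: float
    n_trials_per_day: list[int] = field(default_factory=list)
    milestone_flags: dict = field(default_factory=dict)


def build_daily_heatmap(
    days: list[tuple[object, ProcessedTrace, list[Trial]]],
    layout: SegmentLayout = SegmentLayout(),
    min_trials: int = MIN_TRIALS,
    milestone_flags: dict | None = None,
) -> WarpedHeatmap:
    """Daily-average heatmap over warped rewarded trials.

    ``days`` is an ordered list of ``(day_label, processed_trace, trials)``.
    Days with fewer than ``min_trials`` analyzable trials are skipped (no
    blank row is inserted). Bin values are means over the trials that
    contributed a (non-missing) sample to that bin; bins no trial reached
    stay NaN and are flagged in ``missing_mask``.
    """
    rows, labels, ns = [], [], []
    fs = None
    for label, proc, trials in days:
        fs = proc.fs_hz if fs is None else fs
        if proc.fs_hz != fs:
            raise AlignmentError("all days must share one sampling rate")
        warped = []
        for tr in trials:
            try:
                warped.append(warp_trial(proc, tr.tone_t, tr.np_t, tr.rec_t, layout))
            except AlignmentError:
                continue  # edge-clipped trial dropped
        if len(warped) < min_trials:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            rows.append(np.nanmean(np.array(warped), axis=0))
        labels.append(label)
        ns.append(len(warped))
    if fs is None:
        raise AlignmentError("no days provided")
    rows_arr = (np.array(rows) if rows
                else np.empty((0, layout.n_bins(fs))))
    return WarpedHeatmap(
        rows=rows_arr,
        missing_mask=np.isnan(rows_arr),
        day_labels=labels,
        segment_layout=layout,
        fs_hz=fs,
        n_trials_per_day=ns,
        milestone_flags=milestone_flags or {},
    )


def select_key_days(summaries: list[SessionSummary],
                    threshold: int = 20) -> dict[str, int]:
    """Milestone day indices used to pick heatmap rows across animals.

    Returns only milestones that occur: first/last Pre-Training day, first
    Training day earning >= 10 rewards, acquisition day (first Training day
    from which rewards stay >= ``threshold``), last Training day, last
    Extinction day.
    """
    out: dict[str, int] = {}
    pt = [s.day for s in summaries if s.phase is Phase.PRE_TRAINING]
    tr = [s for s in summaries if s.phase is Phase.TRAINING]
    ext = [s.day for s in summaries if s.phase is Phase.EXTINCTION]
    if pt:
        out["pretrain_first"] = pt[0]
        out["pretrain_last"] = pt[-1]
    ten = [s.day for s in tr if s.rewards >= 10]
    if ten:
        out["first_10_rewards"] = ten[0]
    acq = detect_acquisition(tr, threshold=threshold)
    if acq is not None:
        out["acquisition"] = acq
    if tr:
        out["training_last"] = tr[-1].day
    if ext:
        out["extinction_last"] = ext[-1]
    return out
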