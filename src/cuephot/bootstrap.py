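"""Trial- and mouse-level percentile bootstrap on peri-event waveforms.

For each of ``n_boot`` resamples (default 10,000) rows (trials, or mouse
averages) are drawn with replacement and averaged bin-wise; the two-sided
99% confidence band is the empirical percentile interval of those
resampled means. A bin is significantly different from baseline (Z%dF/F0 =
0) only within runs of at least ``consec_s`` seconds (0.5 s default) where
the band excludes zero. Missing (NaN) bins are excluded bin-wise; bins with
fewer than 3 contributing rows are reported as not analyzable. Joint
correct/incorrect plots downsample the larger trial set to the smaller.
"""
from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .align import PeriEventMatrix

__all__ = [
    "BootstrapLevel",
    "BootstrapParams",
    "BootstrapResult",
    "InsufficientTrialsError",
    "bootstrap_ci",
    "significance_mask",
    "downsample_trials",
]

MIN_ROWS = 3


class BootstrapLevel(str, enum.Enum):
    TRIAL = "TRIAL"
    MOUSE = "MOUSE"


class InsufficientTrialsError(ValueError):
    """Fewer than the minimum number of rows to resample."""


@dataclass(frozen=True)
class BootstrapParams:
    n_boot: int = 10_000
    ci_level: float = 0.99
    consec_s: float = 0.5
    level: BootstrapLevel = BootstrapLevel.TRIAL
    seed: int | None = None

    def validate(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.consec_s < 0:
            raise ValueError("consec_s must be >= 0")


@dataclass
class BootstrapResult:
    """Mean waveform, percentile CI band, and significance mask."""

    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sig_mask: np.ndarray
    params: BootstrapParams
    n_rows: int
    bin_time_s: np.ndarray | None = None
    analyzable: np.ndarray | None = None  # bins with >= MIN_ROWS contributions


def significance_mask(ci_low: np.ndarray, ci_high: np.ndarray,
                      fs: float, consec_s: float) -> np.ndarray:
    """True where the CI excludes zero for at least ``consec_s`` seconds.

    Raw significance is ``ci_low > 0`` or ``ci_high < 0`` (NaN bounds are
    never significant); runs shorter than ``ceil(consec_s * fs)`` bins are
    erased. Both positive- and negative-going exclusions count, so reward
    dips survive the same threshold as peaks.
    """
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    if lo.shape != hi.shape:
        raise ValueError("bound vectors must have equal length")
    with np.errstate(invalid="ignore"):
        raw = (lo > 0) | (hi < 0)
    min_run = max(1, math.ceil(consec_s * fs))
    out = np.zeros_like(raw)
    i = 0
    n = raw.size
    while i < n:
        if raw[i]:
            j = i
            while j < n and raw[j]:
                j += 1
            if j - i >= min_run:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _resample_stats(x: np.ndarray, n_boot: int, rng: np.random.Generator):
    """Bin-wise means of ``n_boot`` with-replacement row resamples."""
    n, b = x.shape
    finite = np.isfinite(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    counts = np.zeros((n_boot, n))
    np.add.at(counts, (np.repeat(np.arange(n_boot), n), idx.ravel()), 1.0)
    if finite.all():
        return (counts @ x) / n
    sums = counts @ np.where(finite, x, 0.0)
    contrib = counts @ finite.astype(float)
    with np.errstate(invalid="ignore"):
        return np.where(contrib > 0, sums / np.where(contrib > 0, contrib, 1.0), np.nan)


def bootstrap_ci(
    m: PeriEventMatrix,
    p: BootstrapParams,
    rng: np.random.Generator | None = None,
    pooled_trials: np.ndarray | None = None,
) -> BootstrapResult:
    """Percentile bootstrap CI of the mean peri-event waveform.

    ``m.values`` rows are trials (TRIAL level) or per-mouse trial averages
    (MOUSE level). At MOUSE level the plotted mean line is computed from
    ``pooled_trials`` (all individual trials stacked) when provided, while
    the CI still resamples the mouse averages. Quantiles use linear
    interpolation. Deterministic for a fixed seed.
    """
    p.validate()
    x = np.asarray(m.values, dtype=float)
    if x.ndim != 2 or x.shape[0] < MIN_ROWS:
        raise InsufficientTrialsError(
            f"need >= {MIN_ROWS} rows to bootstrap, got {0 if x.ndim != 2 else x.shape[0]}"
        )
    if rng is None:
        rng = np.random.default_rng(p.seed)

    finite = np.isfinite(x)
    analyzable = finite.sum(axis=0) >= MIN_ROWS
    boot_means = _resample_stats(x, p.n_boot, rng)
    alpha = (1.0 - p.ci_level) / 2.0
    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if finite.all():  # fast path: plain quantiles on the dense case
            lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha], axis=0)
        else:
            lo, hi = np.nanquantile(boot_means, [alpha, 1.0 - alpha], axis=0)
        mean = np.nanmean(x, axis=0)
    if pooled_trials is not None and p.level is BootstrapLevel.MOUSE:
        pooled = np.asarray(pooled_trials, dtype=float)
        mean = np.nanmean(pooled, axis=0)
    lo = np.where(analyzable, lo, np.nan)
    hi = np.where(analyzable, hi, np.nan)
    mean = np.where(analyzable, mean, np.nan)
    sig = significance_mask(lo, hi, m.fs_hz, p.consec_s)
    return BootstrapResult(
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        sig_mask=sig,
        params=replace(p),
        n_rows=x.shape[0],
        bin_time_s=np.asarray(m.bin_time_s, dtype=float),
        analyzable=analyzable,
    )


def downsample_trials(
    primary_n: int | None,
    other_trials,
    cap: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Seeded uniform subset of ``other_trials`` without replacement.

    The retained count is ``min(primary_n, cap, available)`` over the
    constraints that are given; original trial order is preserved. Used to
    match incorrect-poke trial counts to correct-poke counts and to cap
    per-day trial counts at 20.
    """
    arr = np.asarray(other_trials)
    if arr.shape[0] == 0:
        raise ValueError("other_trials must be nonempty")
    target = arr.shape[0]
    if primary_n is not None:
        target = min(target, int(primary_n))
    if cap is not None:
        target = min(target, int(cap))
    if target == arr.shape[0]:
        return arr
    if rng is None:
        rng = np.random.default_rng()
    idx = np.sort(rng.choice(arr.shape[0], size=target, replace=False))
    return arr[idx]
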