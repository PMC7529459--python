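# Methods

This note documents the models, numerical choices, and design decisions
behind `cuephot`, and what the synthetic-data generators do and do not
emulate.

## Task model

Sessions are 30 min discrete-event simulations. Tones arrive on a
variable-interval schedule drawn **continuous-uniform on [10, 50] s**; the
schedule is specified in the field by its mean (30 s) and range, and the
uniform is the simplest distribution matching both (mean = midpoint,
variance (50−10)²/12 ≈ 133 s²). The tone lasts at most 10 s; a correct
(active-port, tone-on) poke triggers 2 s of reward delivery and the tone
co-terminates with delivery: tone offset = min(onset + 10 s, poke + 2 s).

Intertrial-interval clock semantics: after a rewarded trial the countdown
to the next tone starts at **reward retrieval** (receptacle entry); after
an unanswered tone it starts at tone offset, with a **fresh** draw (the
alternative — reusing the unanswered interval — is unobservable in any
downstream statistic we compute, so the simpler rule is used). In Training,
an incorrect poke outside an active timeout triggers a 5 s timeout, and at
timeout offset the **same interval value re-arms in full** ("restart the
previous intertrial interval" read as restart-the-interval, not
resume-the-remainder). Pokes during an active timeout are logged but do
not retrigger. A consequence worth knowing: a whole interval must elapse
poke-free before a tone can be presented, so Training throughput is
extremely sensitive to the agent's ITI poke rate (see agent defaults).

### Agent

The synthetic animal is a two-state Poisson poker: active-port pokes at
`rate_tone_hz` while the tone is on and `rate_iti_hz` otherwise, an
independent Poisson inactive-port stream, and a lognormal retrieval
latency (median, log-sd). Active poking is suppressed between tone offset
and receptacle entry (the animal is at the receptacle). Pokes during the
tone after the rewarded one are logged as correct pokes without reward, so
correct-poke counts are Poisson-like and the incorrect:correct ratio
tracks (rate ratio) × (duty cycle). Learning is geometric growth of
`rate_tone_hz` across sessions (`learning_gain` per session).

Cohort defaults (chosen once, from the task's behavioral anchors, and
derived analytically from the exponential-latency model):

| phase | rate_tone | rate_iti | rationale |
|---|---|---|---|
| Pre-Training | 0.10 Hz | 0.25 Hz | ~30 rewards/session and roughly an order of magnitude more incorrect than correct pokes |
| Training day d | 0.02·1.6^(d−1) Hz (cap 0.5) | 0.03 Hz | rewards climb from <5 to >25, crossing the 20-reward acquisition criterion mid-Training |
| Extinction | 0.10 Hz | 0.10 Hz | responding persists, no rewards |

Retrieval latency defaults to median 1 s, log-sd 0.4, keeping most trials
inside the 5 s retrieval filter.

What the agent does **not** emulate: poke bursts/bouts (real incorrect
pokes cluster, which is why real mice earn rewards in Training despite
high incorrect counts — a homogeneous Poisson poker cannot, hence the low
Training ITI rate), within-session satiety or warm-up, and any
pharmacological state beyond preset rate changes.

## Stimulation scheduling

Contingent: one train per correct poke at the poke timestamp (25 ms pulses
at 20 Hz for 2 s → 40 pulses); a poke during an active train does not
retrigger (single-laser hardware). Non-contingent (yoked): trains are
queued at nominal request times and released at the first instant t
satisfying **all** of: no nose poke in [t−2 s, t]; no tone onset in
[t, t+2 s]; and ≥5 s since the most recent rewarded receptacle entry (or
no reward earned yet). The conjunctive reading is a deliberate choice —
the disjunctive reading of the rule list would let a single satisfied
clause release a train right after a poke, defeating the stated purpose of
unpairing stimulation from task events. Trains additionally never overlap
a tone, a reward-delivery window, or each other; infeasible trains at
session end are dropped and counted in the log metadata.

## Photometry generator

signal = B·(1 + drift)·(1 + Σ A·k) + motion + noise, reference =
B·(1 + drift) + motion + independent noise, with B the baseline (default
100 a.u.), drift a fractional polynomial in t/T (order 1 or 2; polynomial
rather than exponential so a matching-order baseline fit removes it
exactly in noise-free tests), and k a causal difference-of-exponentials
kernel (rise 0.2 s, decay 1 s, peak-normalized; time-to-peak
rise·decay/(decay−rise)·ln(decay/rise) ≈ 0.40 s). Transients are
multiplicative so %ΔF/F0 amplitudes are drift-invariant. Traces are
generated directly at the post-decimation rate (120 S/s = 12 kS/s ÷ 100);
a raw-rate trace can be built and decimated to exercise that operation.

Stage presets give each learning stage an amplitude schedule (fractions of
baseline): Pre-Training is poke-locked (0.05 at the correct poke, −0.02
dip delayed 2.5 s, 0.012 at retrieval), early Training retrieval-locked
(0.05), acquired tone-locked (0.05 tone, poke reduced to 0.015),
Extinction a weakened tone response; CAMKII variants are retrieval-locked
until acquisition then tone-locked, with small negative deflections after
incorrect pokes. The Pre-Training retrieval amplitude is kept well below
the poke amplitude so the stage's dominant anchor is unambiguous after
warped averaging (the poke kernel's 0.4 s peak delay rides into the
retrieval segment on short-latency trials). Reference-channel mirroring of
the indicator (seen with some calcium sensors) is not emulated.

## Preprocessing

"Least-squares baseline" is ordinary least squares polynomial fitting of
the stated order over the whole session (an adaptive-filter reading is
rejected: one baseline per session). The fit uses a domain-mapped
polynomial basis, making it well conditioned and invariant to time-origin
shifts. %ΔF/F0 = 100·(F − F0)/F0 pointwise; F0 ≤ 0 anywhere is an error
(pathological trace), as is a non-finite input or a zero-variance %ΔF/F0.
The Z-score uses the **population** SD (with ~216,000 samples the
sample/population difference is <0.01%, but the choice is fixed so tests
can be exact). Decimation is by non-overlapping block means (mean
filtering is a crude anti-alias; naive subsampling would fold noise), with
a trailing partial block dropped. Channels are processed independently; no
reference-channel subtraction is performed by default.

## Alignment and warping

Fixed-window extraction spans [−5 s, +10 s) around an event under a
half-open bin convention (bin i at offset −5 + i/fs); events whose window
crosses a session edge are dropped, and fewer than 3 surviving trials
means nothing-to-analyze. Rewarded-trial filtering requires receptacle
entry within 5 s of the poke; incorrect-poke analysis keeps only pokes
with no incorrect poke in the preceding 5 s (against the raw sequence).

The three-anchor warp is the single most consequential interpretation in
the package. Each trial contributes: 5 s verbatim before tone onset; its
tone→poke samples **evenly split** into a fixed 4 s budget — half the
samples (the extra one on the leading side) laid forward from tone onset,
half backward from the poke — leaving explicitly-missing center bins when
latency < 4 s; likewise poke→retrieval into a 1 s budget; then 5 s
verbatim after retrieval. Over-budget latencies are center-cropped
symmetrically. This dual-anchor split is chosen because the documented
blank "added for alignment" bins are incompatible with per-trial
resampling onto a fixed grid (resampling leaves no blanks); the warp is
isolated in one function (`warp_trial`) so a resampling variant can be
swapped in for sensitivity analysis. When latency equals the budget the
segment is copied verbatim (the warp is mean-preserving there). Daily
heatmap rows are bin-wise means over non-missing values from ≥3 retained
trials; days below the gate are skipped, never blank-padded, and no
interpolation is ever applied over missing bins. Rewarded-trial heatmaps
have no Extinction rows by construction (no rewards → no qualifying
trials → skipped rows).

## Bootstrap inference

Percentile bootstrap (not BCa), 10,000 resamples by default: rows (trials,
or per-mouse trial averages at mouse level) are drawn with replacement at
the original count and averaged bin-wise; the two-sided 99% band is the
empirical [0.5%, 99.5%] interval using linear-interpolation quantiles
(the order-statistic alternative is flagged for sensitivity testing; at
10,000 resamples the two differ by less than one resample-distribution
step). Missing bins are excluded bin-wise from resampled means; a bin with
fewer than 3 contributing rows is reported not-analyzable rather than
(in)significant. Significance requires the band to exclude zero over runs
of at least ceil(0.5 s · fs) bins, evaluated on the raw mask with no
smoothing; negative-going exclusions (dips) count the same as peaks. At
mouse level the band resamples mouse averages while the plotted mean line
is the pooled mean of all individual trials. Downsampling (matching
incorrect to correct trial counts; capping per-day trials at 20) is a
seeded uniform subset without replacement, recorded in result metadata.

Percentile bootstraps undercover at small n: on i.i.d. Gaussian nulls with
n = 30 trials a single-bin "99%" interval excludes zero in roughly 1–3% of
replicates. The 0.5 s consecutive threshold is what keeps the per-session
false-alarm rate low (≈0/100 null sessions in the calibration test):
white-noise bins essentially never stay significant for 60 consecutive
bins at 120 S/s.

## Behavior statistics

Acquisition ("consistently earning ≥20 rewards") is formalized as a
suffix rule: the first Training day from which every later Training day
also reaches the threshold. It is deterministic, order-robust, and
invariant to improving post-acquisition performance. The two-group sample
size uses the normal approximation without t-correction,
n = ceil(2σ²(z₁₋α/₂ + z_power)²/Δ²) with a floor of 2; repeated-measures
ANOVAs are deliberately out of scope — the package exports tidy
per-session tables for external statistics software instead.

## Problem sizes and determinism

Every stochastic component takes an explicit seed (one generator per
session; cohort helpers spawn per-day seeds below 2³¹ from the cohort
seed), and rerunning any pipeline configuration is bit-identical. The
calibration and dynamics tests use full-length 30 min sessions at
120 S/s with 10,000 bootstrap resamples; detection calibration uses 100
seeded sessions per condition and the learning-dynamics check three
simulated animals, sizes at which the measured rates are stable to a few
percent.

## Known limitations

- The Poisson agent reproduces rates and learning curves, not poke-bout
  microstructure or reaction-time distributions.
- The generator's transients are noiseless in amplitude (no trial-to-trial
  gain variability) and the kernel is stage-independent.
- Bleaching is polynomial by default; real exponential bleaching leaves a
  small residual under a polynomial fit (an exponential drift mode exists
  to exercise exactly that mismatch).
- Passing the round-trip tests shows the chain recovers what the generator
  injects under these assumptions; it does not certify performance on real
  recordings with motion artifacts or sensor nonlinearity.
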