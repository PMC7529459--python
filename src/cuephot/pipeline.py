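"""Cohort simulation and the end-to-end pipeline runner.

``simulate_mouse`` strings daily sessions together (Pre-Training ->
Training -> Extinction) with a learning agent whose tone-poke rate grows
geometrically across Training days, assigns each day a photometry stage
(nose-poke-locked in Pre-Training, retrieval-locked before acquisition,
tone-locked from the acquisition day, tone-locked/decaying in Extinction),
and synthesizes the matching traces. ``run_pipeline`` executes simulate ->
preprocess -> align -> bootstrap -> summarize from one config and writes
every artifact plus a manifest; reruns with the same config are
bit-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .align import (SegmentLayout, Trial, build_daily_heatmap,
                    extract_peri_event, filter_rewarded_trials, select_key_days)
from .behavior import SessionSummary, detect_acquisition, summarize_session
from .bootstrap import BootstrapLevel, BootstrapParams, bootstrap_ci
from .events import EventLog, Phase, validate_event_log
from .io import (write_bootstrap_csv, write_event_log, write_heatmap,
                 write_summaries_csv, write_trace_h5)
from .preprocess import Channel, ProcessedTrace, process_trace
from .synth import LearningStage, PhotoParams, RawTrace, synthesize_trace
from .task import AgentParams, TaskConfig

__all__ = [
    "CohortSpec",
    "DayRecord",
    "MouseData",
    "PipelineConfig",
    "simulate_mouse",
    "run_pipeline",
]

log_ = logging.getLogger(__name__)

# Agent anchors chosen from the behavioral shape of the task: Pre-Training
# animals poke heavily but indiscriminately (roughly eightfold more
# incorrect than correct pokes, most rewards obtained within a few days);
# Training starts with suppressed responding and the tone rate grows until
# the >= 20-rewards acquisition criterion is crossed mid-Training.
PRETRAIN_AGENT = AgentParams(rate_tone_hz=0.1, rate_iti_hz=0.25)
# Under the timeout rule a whole interval must pass poke-free before the
# next tone, so Training animals must suppress ITI responding; 0.03 Hz keeps
# incorrect pokes frequent while still letting tones through.
TRAINING_AGENT = AgentParams(rate_tone_hz=0.02, rate_iti_hz=0.03, learning_gain=1.6)
EXTINCTION_AGENT = AgentParams(rate_tone_hz=0.1, rate_iti_hz=0.1)
MAX_RATE_TONE_HZ = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Study-design defaults for one simulated animal."""

    n_pretrain: int = 5
    n_training: int = 8
    n_extinction: int = 2
    task: TaskConfig = TaskConfig()
    photo: PhotoParams = PhotoParams()
    sensor: str = "ACH"  # "ACH" or "CAMKII" stage-preset family
    seed: int = 0


@dataclass
class DayRecord:
    day: int
    phase: Phase
    log: EventLog
    trace: RawTrace
    stage: LearningStage
    summary: SessionSummary


@dataclass
class MouseData:
    days: list[DayRecord]
    acquisition_day: int | None

    @property
    def summaries(self) -> list[SessionSummary]:
        return [d.summary for d in self.days]


def _stage_for(phase: Phase, day: int, acq: int | None, sensor: str) -> LearningStage:
    prefix = "CAMKII_" if sensor.upper() == "CAMKII" else ""
    if phase is Phase.PRE_TRAINING:
        return LearningStage(prefix + "PRETRAIN")
    if phase is Phase.EXTINCTION:
        return LearningStage(prefix + "EXTINCTION")
    if acq is not None and day >= acq:
        return LearningStage(prefix + "ACQUIRED")
    return LearningStage(prefix + "EARLY_TRAIN")


def simulate_mouse(spec: CohortSpec) -> MouseData:
    """Simulate one animal's full paradigm and synthesize its photometry.

    Behavior is simulated first for all days; acquisition is then detected
    from the reward counts (suffix rule) and decides on which Training day
    the transient schedule switches from retrieval-locked to tone-locked.
    """
    rng = np.random.default_rng(spec.seed)
    plan: list[tuple[Phase, AgentParams]] = []
    for d in range(spec.n_pretrain):
        plan.append((Phase.PRE_TRAINING, PRETRAIN_AGENT))
    for d in range(spec.n_training):
        a = TRAINING_AGENT.after_sessions(d)
        a = replace(a, rate_tone_hz=min(a.rate_tone_hz, MAX_RATE_TONE_HZ))
        plan.append((Phase.TRAINING, a))
    for d in range(spec.n_extinction):
        plan.append((Phase.EXTINCTION, EXTINCTION_AGENT))

    logs: list[EventLog] = []
    summaries: list[SessionSummary] = []
    from .task import simulate_session

    for day, (phase, agent) in enumerate(plan, start=1):
        task = replace(spec.task, phase=phase)
        session_rng = np.random.default_rng(rng.integers(0, 2**31))
        log = simulate_session(task, agent, rng=session_rng,
                               session_id=f"day{day:02d}")
        validate_event_log(log)
        logs.append(log)
        summaries.append(summarize_session(log, day=day))

    acq = detect_acquisition(summaries, threshold=spec.task.acquisition_threshold_rewards)

    days: list[DayRecord] = []
    for day, log in enumerate(logs, start=1):
        stage = _stage_for(log.phase, day, acq, spec.sensor)
        photo = replace(spec.photo, seed=None)
        trace_rng = np.random.default_rng(rng.integers(0, 2**31))
        trace = synthesize_trace(log, photo, stage, rng=trace_rng)
        days.append(DayRecord(day=day, phase=log.phase, log=log, trace=trace,
                              stage=stage, summary=summaries[day - 1]))
    return MouseData(days=days, acquisition_day=acq)


@dataclass
class PipelineConfig:
    """Everything one deterministic pipeline run needs."""

    out_dir: str = "runs/demo"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit_order: int = 1
    layout: SegmentLayout = field(default_factory=SegmentLayout)
    bootstrap: BootstrapParams = field(default_factory=BootstrapParams)
    max_retrieval_s: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        c, p, b, l = self.cohort, self.cohort.photo, self.bootstrap, self.layout
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "fit_order": self.fit_order,
            "max_retrieval_s": self.max_retrieval_s,
            "cohort": {
                "n_pretrain": c.n_pretrain, "n_training": c.n_training,
                "n_extinction": c.n_extinction, "sensor": c.sensor,
                "seed": c.seed,
                "task": {
                    "session_duration_s": c.task.session_duration_s,
                    "vi_mean_s": c.task.vi_mean_s,
                    "vi_min_s": c.task.vi_min_s,
                    "vi_max_s": c.task.vi_max_s,
                },
                "photo": {
                    "fs_hz": p.fs_hz, "baseline_au": p.baseline_au,
                    "bleach_coeffs": list(p.bleach_coeffs),
                    "noise_sd_au": p.noise_sd_au,
                },
            },
            "layout": {
                "pre_tone_s": l.pre_tone_s,
                "tone_np_budget_s": l.tone_np_budget_s,
                "np_rec_budget_s": l.np_rec_budget_s,
                "post_rec_s": l.post_rec_s,
            },
            "bootstrap": {
                "n_boot": b.n_boot, "ci_level": b.ci_level,
                "consec_s": b.consec_s, "level": b.level.value,
            },
        }

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls()
        cohort_raw = raw.get("cohort", {})
        task = replace(TaskConfig(), **cohort_raw.get("task", {}))
        photo_raw = dict(cohort_raw.get("photo", {}))
        if "bleach_coeffs" in photo_raw:
            photo_raw["bleach_coeffs"] = tuple(photo_raw["bleach_coeffs"])
        photo = replace(PhotoParams(), **photo_raw)
        cohort = CohortSpec(
            n_pretrain=cohort_raw.get("n_pretrain", 5),
            n_training=cohort_raw.get("n_training", 8),
            n_extinction=cohort_raw.get("n_extinction", 2),
            task=task, photo=photo,
            sensor=cohort_raw.get("sensor", "ACH"),
            seed=cohort_raw.get("seed", raw.get("seed", 0)),
        )
        return cls(
            out_dir=raw.get("out_dir", cfg.out_dir),
            cohort=cohort,
            fit_order=raw.get("fit_order", 1),
            layout=SegmentLayout(**raw.get("layout", {})),
            bootstrap=BootstrapParams(
                **{**raw.get("bootstrap", {}), "seed": raw.get("seed", 0),
                   "level": BootstrapLevel(
                       raw.get("bootstrap", {}).get("level", "TRIAL"))}
            ),
            max_retrieval_s=raw.get("max_retrieval_s", 5.0),
            seed=raw.get("seed", 0),
        )

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """simulate -> preprocess -> align -> bootstrap -> summarize, on disk.

    Writes per-day event logs and traces, the per-day correct-poke
    bootstrap result for the last Pre-Training day, the warped daily
    heatmap, the tidy behavior table, and a manifest carrying the config
    hash, seeds, and package version. Returns the artifact paths plus the
    in-memory results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}

    t0 = time.perf_counter()
    cohort = replace(cfg.cohort, seed=cfg.cohort.seed if cfg.cohort.seed else cfg.seed)
    mouse = simulate_mouse(cohort)
    stages["simulate_s"] = time.perf_counter() - t0
    log_.info("simulate: %d days in %.2fs", len(mouse.days), stages["simulate_s"])

    t0 = time.perf_counter()
    for rec in mouse.days:
        write_event_log(rec.log, out / f"events_day{rec.day:02d}.csv")
        write_trace_h5(rec.trace, out / f"trace_day{rec.day:02d}.h5")
    stages["write_raw_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    processed: dict[int, ProcessedTrace] = {
        rec.day: process_trace(rec.trace, order=cfg.fit_order, channel=Channel.SIGNAL)
        for rec in mouse.days
    }
    stages["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    day_trials = [
        (rec.day, processed[rec.day],
         filter_rewarded_trials(rec.log, cfg.max_retrieval_s))
        for rec in mouse.days
    ]
    milestones = select_key_days(
        mouse.summaries, threshold=cohort.task.acquisition_threshold_rewards)
    heatmap = build_daily_heatmap(day_trials, cfg.layout,
                                  milestone_flags=milestones)
    write_heatmap(heatmap, out / "heatmap.csv")
    stages["align_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pt_last = max((r for r in mouse.days if r.phase is Phase.PRE_TRAINING),
                  key=lambda r: r.day, default=None)
    bci = None
    if pt_last is not None:
        trials = filter_rewarded_trials(pt_last.log, cfg.max_retrieval_s)
        mat = extract_peri_event(processed[pt_last.day],
                                 np.array([t.np_t for t in trials]))
        if mat is not None:
            bci = bootstrap_ci(mat, replace(cfg.bootstrap, seed=cfg.seed))
            write_bootstrap_csv(bci, out / "bci_correct_pt_last.csv")
    stages["bootstrap_s"] = time.perf_counter() - t0

    write_summaries_csv(mouse.summaries, out / "behavior.csv")

    for name, dt in stages.items():
        log_.info("stage %s took %.3f s", name, dt)  # informational only
    cfg_yaml = cfg.to_yaml(out / "config.yaml")
    cfg_hash = hashlib.sha256(cfg_yaml.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "config_sha256": cfg_hash,
        "seed": cfg.seed,
        "acquisition_day": mouse.acquisition_day,
        "milestones": milestones,
        "n_days": len(mouse.days),
        "heatmap_rows": int(heatmap.rows.shape[0]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "out_dir": out,
        "mouse": mouse,
        "heatmap": heatmap,
        "bci": bci,
        "milestones": milestones,
        "manifest": manifest,
    }
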