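"""Seed-fixed simulation benchmarks for the detector.

The default trajectory benchmark emulates the study cohort at desk scale:
12 "mutant" sessions with frequent sleep myoclonus (4 jerks/h) and 12
wild-type-like sessions with sporadic twitches (0.2 jerks/h), each a 4-h
recording at 25 Hz scored over its last three hours.  The video benchmark
is a reduced (10-min, 5 px/cm) simulate -> render -> track -> detect chain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import SessionSummary, detect_events
from .report import MatchResult, match_events, summarize_cohort
from .simulate import GroundTruth, SimulationConfig, simulate_session
from .states import DetectionConfig

MUTANT_JERK_RATE_PER_H = 4.0
WT_JERK_RATE_PER_H = 0.2


@dataclass
class BenchmarkResult:
    match: MatchResult                       # pooled over all sessions
    summaries: list[SessionSummary]
    design: pd.DataFrame
    per_session: list[MatchResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "match": self.match.to_dict(),
            "sessions": [s.to_dict() for s in self.summaries],
        }


def run_session(
    sim_cfg: SimulationConfig,
    det_cfg: DetectionConfig,
) -> tuple[SessionSummary, MatchResult, GroundTruth]:
    """Simulate one session, detect, and match against injected truth.

    Matching is restricted to ground-truth jerks inside the analysis window
    (events in the discarded first hour are out of scope by design).
    """
    series, truth = simulate_session(sim_cfg)
    events, summary = detect_events(series, det_cfg)
    truth_onsets = truth.jerk_times(det_cfg.analysis_start_s, det_cfg.analysis_end_s)
    detected = [ev for ev in events if ev.accepted]
    match = match_events(detected, truth_onsets, tolerance_s=2.0)
    return summary, match, truth

def default_benchmark(
    seed: int = 0,
    n_per_group: int = 12,
    duration_s: float = 14400.0,
    mutant_rate: float = MUTANT_JERK_RATE_PER_H,
    wt_rate: float = WT_JERK_RATE_PER_H,
    det_cfg: DetectionConfig | None = None,
) -> BenchmarkResult:
    """Run the two-group trajectory-mode benchmark (deterministic per seed)."""
    det_cfg = det_cfg or DetectionConfig(
        analysis_end_s=min(14400.0, duration_s),
        analysis_start_s=min(3600.0, duration_s / 4.0),
    )
    summaries: list[SessionSummary] = []
    per_session: list[MatchResult] = []
    design_rows = []
    tp = fp = fn = 0
    errors: list[float] = []
    for g, (genotype, rate) in enumerate([("mutant", mutant_rate), ("wt", wt_rate)]):
        for i in range(n_per_group):
            sid = f"{genotype}_{i:02d}"
            sim_cfg = SimulationConfig(
                duration_s=duration_s,
                seed=int(np.random.SeedSequence([seed, g, i]).generate_state(1)[0] % (2**31)),
                jerk_rate_per_h=rate,
                session_id=sid,
            )
            summary, match, _ = run_session(sim_cfg, det_cfg)
            summaries.append(summary)
            per_session.append(match)
            design_rows.append({"session_id": sid, "subject": sid,
                                "genotype": genotype, "age": "single"})
            tp += match.tp
            fp += match.fp
            fn += match.fn
            errors.extend(match.onset_errors_s)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    pooled = MatchResult(tp, fp, fn, precision, recall, f1, errors, 2.0)
    return BenchmarkResult(
        match=pooled, summaries=summaries,
        design=pd.DataFrame(design_rows), per_session=per_session)


@dataclass
class VideoBenchmarkResult:
    match: MatchResult
    centroid_rmse_cm: float
    body_angle_mae_deg: float
    elongation_mae_pct: float
    n_frames: int


def video_benchmark(
    seed: int = 0,
    duration_s: float = 600.0,
    px_per_cm: float = 5.0,
    jerk_rate_per_h: float = 60.0,
) -> VideoBenchmarkResult:
    """Reduced end-to-end video benchmark: simulate -> render -> track -> detect.

    A 10-min sleep-dominated session with a high jerk rate (so the short
    window holds ~8-10 events), rendered at 5 px/cm and re-tracked from the
    pixels; detection runs on the tracked series with pixel-change mobility.
    Tracker errors are computed against the simulated series on frames where
    both are defined.
    """
    from .simulate import render_frames
    from .tracker import track_video

    sim_cfg = SimulationConfig(
        duration_s=duration_s,
        seed=seed,
        initial_explore_s=30.0,
        explore_bout_mean_s=20.0,
        sleep_bout_mean_s=300.0,
        groom_bout_mean_s=15.0,
        jerk_rate_per_h=jerk_rate_per_h,
        dropout_prob_per_sample=0.0,
        session_id="video",
    )
    series, truth = simulate_session(sim_cfg)
    frames = render_frames(series, px_per_cm=px_per_cm)
    tracked, mobility = track_video(frames, px_per_cm=px_per_cm,
                                    sample_rate_hz=sim_cfg.sample_rate_hz)
    det_cfg = DetectionConfig(analysis_start_s=30.0, analysis_end_s=duration_s)
    events, _ = detect_events(tracked, det_cfg, mobility=mobility)
    truth_onsets = truth.jerk_times(det_cfg.analysis_start_s, det_cfg.analysis_end_s)
    match = match_events([e for e in events if e.accepted], truth_onsets,
                         tolerance_s=2.0)
    ok = ~np.isnan(tracked.center_xy).any(axis=1) & ~np.isnan(series.center_xy).any(axis=1)
    d = np.linalg.norm(tracked.center_xy[ok] - series.center_xy[ok], axis=1)
    rmse = float(np.sqrt(np.mean(d ** 2)))
    angle_mae = float(np.nanmean(np.abs(
        tracked.body_angle_deg[ok] - series.body_angle_deg[ok])))
    elong_mae = float(np.nanmean(np.abs(
        tracked.elongation_pct[ok] - series.elongation_pct[ok])))
    return VideoBenchmarkResult(
        match=match, centroid_rmse_cm=rmse, body_angle_mae_deg=angle_mae,
        elongation_mae_pct=elong_mae, n_frames=len(frames))
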