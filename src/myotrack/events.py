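"""Myoclonic-event detection, classification, pairing and counting.

A candidate jerk is a short velocity burst of a quiescent animal:

(a) a maximal run of raw center velocity above ``burst_vel_min_cms``
    (runs separated by less than ``merge_gap_s`` are merged, largest peak
    kept) no longer than ``burst_max_dur_s``;
(b) peak velocity within the ``[burst_vel_min_cms, burst_vel_max_cms]`` band;
(c) a contiguous Immobile mobility run of at least ``pre_immobile_min_s``
    ending no more than ``pre_immobile_gap_max_s`` before burst onset;
(d) Multi Condition 1 and/or Multi Condition 2 true at >= 1 sample within
    the burst padded by ``mc_pad_s``.

Candidates are then auto-classified: events riding on voluntary locomotion
are rejected (the automated stand-in for confirm-by-eye review), everything
else is accepted.  Movement *after* the event never rejects — animals
typically move around briefly while recovering from a jerk.  Consecutive
accepted events 1-20 s apart are tagged as pairs but still count as two
events, and only events with onset inside the analysis window (by default
the last three hours of a 4-h recording) are counted.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Signal, TrackingSeries
from .states import AnalysisProfile, DetectionConfig, Mobility, compute_profile


@dataclass
class MyoclonicEvent:
    """One detected candidate/event."""

    onset_s: float
    offset_s: float
    onset_idx: int
    offset_idx: int            # inclusive last sample of the burst
    peak_velocity_cms: float
    pre_immobile_s: float      # Immobile run length immediately before onset
    mc1_hit: bool
    mc2_hit: bool
    accepted: bool = False
    rejection_reason: str = ""
    pair_id: int | None = None
    magnitude_class: str = ""  # modest / large, split at the band midpoint

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _immobile_runs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run_start_index, run_length) arrays for contiguous Immobile runs."""
    imm = codes == Mobility.IMMOBILE
    if not imm.any():
        return np.empty(0, int), np.empty(0, int)
    d = np.diff(imm.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    ends = np.where(d == -1)[0] + 1
    if imm[0]:
        starts = np.concatenate(([0], starts))
    if imm[-1]:
        ends = np.concatenate((ends, [len(imm)]))
    return starts, ends - starts


def _pre_immobile(
    onset_idx: int,
    codes: np.ndarray,
    run_starts: np.ndarray,
    run_lens: np.ndarray,
    dt: float,
    gap_max_s: float,
) -> float:
    """Length (s) of the Immobile run ending within ``gap_max_s`` before onset.

    Returns 0.0 when no Immobile sample falls close enough before onset.
    """
    run_ends = run_starts + run_lens  # exclusive
    k = np.searchsorted(run_ends, onset_idx, side="right") - 1
    # the run may contain the onset (immobile up to the burst): clip its end
    j = np.searchsorted(run_starts, onset_idx, side="right") - 1
    if j >= 0 and run_starts[j] < onset_idx and run_ends[j] > onset_idx:
        end = onset_idx
        start = run_starts[j]
    elif k >= 0:
        end = run_ends[k]
        start = run_starts[k]
    else:
        return 0.0
    gap_s = (onset_idx - end) * dt
    if gap_s > gap_max_s:
        return 0.0
    return (end - start) * dt


def detect_candidates(
    series: TrackingSeries,
    cfg: DetectionConfig,
    profile: AnalysisProfile | None = None,
) -> list[MyoclonicEvent]:
    """Scan the analysis window for burst candidates (accepted flag unset).

    Applies criteria (a)-(d) from the module docstring to maximal
    above-threshold velocity runs within ``[analysis_start_s,
    analysis_end_s]``; a window extending past the recording is clipped with
    a warning.  Candidates are returned sorted by onset.
    """
    if profile is None:
        profile = compute_profile(series, cfg)
    ser = profile.series
    n = len(ser)
    dt = ser.dt
    t = ser.t
    if ser.duration_s < cfg.analysis_end_s - 1e-9:
        warnings.warn(
            f"recording ({ser.duration_s:.0f} s) shorter than analysis window "
            f"end ({cfg.analysis_end_s:.0f} s); window clipped", stacklevel=2)
    in_window = (t >= cfg.analysis_start_s) & (t <= cfg.analysis_end_s)
    v = profile.velocity.values
    with np.errstate(invalid="ignore"):
        above = (v > cfg.burst_vel_min_cms) & in_window
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)
    # merge runs separated by less than merge_gap_s (fragments of one jerk)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (t[s] - t[merged[-1][1] - 1]) < cfg.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    codes = profile.mobility_states.values
    run_starts, run_lens = _immobile_runs(codes)
    pad = int(round(cfg.mc_pad_s * ser.sample_rate_hz))
    mc_any = profile.mc1.values | profile.mc2.values
    out: list[MyoclonicEvent] = []
    for s, e in merged:
        dur = (e - s) * dt
        if dur > cfg.burst_max_dur_s:                       # (a)
            continue
        peak = float(np.nanmax(v[s:e]))
        if not (cfg.burst_vel_min_cms <= peak <= cfg.burst_vel_max_cms):  # (b)
            continue
        pre = _pre_immobile(s, codes, run_starts, run_lens, dt,
                            cfg.pre_immobile_gap_max_s)
        if pre < cfg.pre_immobile_min_s:                    # (c)
            continue
        lo, hi = max(0, s - pad), min(n, e + pad)
        if not mc_any[lo:hi].any():                         # (d)
            continue
        out.append(MyoclonicEvent(
            onset_s=float(t[s]),
            offset_s=float(t[e - 1]) + dt,
            onset_idx=int(s),
            offset_idx=int(e - 1),
            peak_velocity_cms=peak,
            pre_immobile_s=float(pre),
            mc1_hit=bool(profile.mc1.values[lo:hi].any()),
            mc2_hit=bool(profile.mc2.values[lo:hi].any()),
        ))
    return out


def classify_candidate(
    candidate: MyoclonicEvent,
    series: TrackingSeries,
    cfg: DetectionConfig,
    profile: AnalysisProfile | None = None,
) -> MyoclonicEvent:
    """Accept or reject one candidate (automated voluntary-movement screen).

    Rejects when (i) the animal was Mobile/HighlyMobile for more than half
    of the 5 s before onset ("walking-in"); (ii) the burst displaces the
    center by more than 10 cm with no in-burst velocity spike exceeding
    1.5x the pre-burst 10-s maximum ("sustained locomotion, no spike");
    (iii) the padded burst overlaps an unresolvable tracking gap.  Post-event
    locomotion never rejects.  Also fills ``magnitude_class``.
    """
    if profile is None:
        profile = compute_profile(series, cfg)
    ser = profile.series
    rate = ser.sample_rate_hz
    dt = ser.dt
    s, e = candidate.onset_idx, candidate.offset_idx + 1
    reason = ""
    # (iii) unresolvable gap overlapping the padded burst
    pad = int(round(cfg.mc_pad_s * rate))
    lo, hi = max(0, s - pad), min(len(ser), e + pad)
    if (~profile.valid[lo:hi]).any():
        reason = "invalid-gap"
    # (i) walking-in
    if not reason:
        w = int(round(cfg.walkin_window_s * rate))
        pre = profile.mobility_states.values[max(0, s - w):s]
        if len(pre) and np.mean(pre != Mobility.IMMOBILE) > cfg.walkin_mobile_frac:
            reason = "walking-in"
    # (ii) sustained locomotion without a spike
    if not reason:
        net = float(np.linalg.norm(ser.center_xy[min(e, len(ser)) - 1] - ser.center_xy[s]))
        if net > cfg.locomotion_net_disp_cm:
            lb = int(round(cfg.locomotion_lookback_s * rate))
            prev = profile.velocity.values[max(0, s - lb):s]
            prev_max = float(np.nanmax(prev)) if len(prev) and np.isfinite(prev).any() else 0.0
            burst_max = float(np.nanmax(profile.velocity.values[s:e]))
            if not burst_max > cfg.locomotion_spike_ratio * prev_max:
                reason = "sustained-locomotion"
    midpoint = 0.5 * (cfg.burst_vel_min_cms + cfg.burst_vel_max_cms)
    return dataclasses.replace(
        candidate,
        accepted=(reason == ""),
        rejection_reason=reason,
        magnitude_class="large" if candidate.peak_velocity_cms >= midpoint else "modest",
    )


def pair_consecutive(
    events: list[MyoclonicEvent], cfg: DetectionConfig
) -> list[MyoclonicEvent]:
    """Tag consecutive accepted events 1-20 s apart with a shared pair id.

    Pairing is greedy left-to-right over onset-sorted accepted events; an
    event belongs to at most one pair and both members still count as
    separate events.
    """
    out = [dataclasses.replace(ev, pair_id=None) for ev in events]
    accepted = [ev for ev in out if ev.accepted]
    accepted.sort(key=lambda ev: ev.onset_s)
    pid = 0
    i = 0
    while i + 1 < len(accepted):
        gap = accepted[i + 1].onset_s - accepted[i].onset_s
        if cfg.pair_min_gap_s <= gap <= cfg.pair_max_gap_s:
            accepted[i].pair_id = pid
            accepted[i + 1].pair_id = pid
            pid += 1
            i += 2
        else:
            i += 1
    return out


@dataclass
class SessionSummary:
    """Per-session event tally over the analysis window."""

    session_id: str
    count: int
    window_hours: float
    rate_per_hour: float
    n_modest: int
    n_large: int
    n_paired: int
    n_rejected: int
    mc2_available: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def count_events(
    events: list[MyoclonicEvent],
    cfg: DetectionConfig,
    session_id: str = "",
    duration_s: float | None = None,
    mc2_available: bool = True,
) -> SessionSummary:
    """Tally accepted events with onset inside the analysis window."""
    end = cfg.analysis_end_s if duration_s is None else min(cfg.analysis_end_s, duration_s)
    hours = max(end - cfg.analysis_start_s, 0.0) / 3600.0
    acc = [ev for ev in events if ev.accepted
           and cfg.analysis_start_s <= ev.onset_s <= cfg.analysis_end_s]
    return SessionSummary(
        session_id=session_id,
        count=len(acc),
        window_hours=hours,
        rate_per_hour=len(acc) / hours if hours > 0 else 0.0,
        n_modest=sum(ev.magnitude_class == "modest" for ev in acc),
        n_large=sum(ev.magnitude_class == "large" for ev in acc),
        n_paired=sum(ev.pair_id is not None for ev in acc),
        n_rejected=sum((not ev.accepted) for ev in events),
        mc2_available=mc2_available,
    )


def detect_events(
    series: TrackingSeries,
    cfg: DetectionConfig | None = None,
    mobility: Signal | None = None,
) -> tuple[list[MyoclonicEvent], SessionSummary]:
    """Full per-session pipeline: profile -> candidates -> classify -> pair -> count."""
    cfg = cfg or DetectionConfig()
    profile = compute_profile(series, cfg, mobility=mobility)
    candidates = detect_candidates(series, cfg, profile=profile)
    classified = [classify_candidate(c, series, cfg, profile=profile) for c in candidates]
    paired = pair_consecutive(classified, cfg)
    summary = count_events(paired, cfg, session_id=series.session_id,
                           duration_s=series.duration_s,
                           mc2_available=profile.mc2_available)
    return paired, summary


def events_to_frame(events: list[MyoclonicEvent], session_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "session_id": session_id,
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "peak_velocity_cms": ev.peak_velocity_cms,
                "pre_immobile_s": ev.pre_immobile_s,
                "mc1": int(ev.mc1_hit),
                "mc2": int(ev.mc2_hit),
                "accepted": int(ev.accepted),
                "rejection_reason": ev.rejection_reason,
                "pair_id": ev.pair_id if ev.pair_id is not None else "",
                "magnitude_class": ev.magnitude_class,
            }
            for ev in events
        ],
        columns=[
            "session_id", "onset_s", "offset_s", "peak_velocity_cms",
            "pre_immobile_s", "mc1", "mc2", "accepted", "rejection_reason",
            "pair_id", "magnitude_class",
        ],
    )


def write_events_csv(events: list[MyoclonicEvent], path, session_id: str = "") -> str:
    events_to_frame(events, session_id).to_csv(path, index=False)
    return str(path)


def write_events_json(
    events: list[MyoclonicEvent], path, cfg: DetectionConfig, session_id: str = ""
) -> str:
    """JSON export with the resolved config embedded for provenance."""
    payload = {
        "session_id": session_id,
        "config": cfg.to_dict(),
        "events": [dataclasses.asdict(ev) for ev in events],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    return str(path)
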