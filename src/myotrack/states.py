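"""Analysis-profile state classifiers.

These reproduce the per-sample classifiers of the video-tracking analysis
profile used for jerk screening:

* ``movement_state`` — two-threshold (start/stop) hysteresis Moving state.
* ``mobility_raw`` / ``mobility_state`` — a mobility percentage smoothed
  over 15 samples and split into Immobile / Mobile / HighlyMobile.
* ``multi_condition_1`` — Moving (3.20/2.25 cm/s) AND 100-sample mean center
  velocity <= 0.45 cm/s AND elongation <= 75% AND body angle <= 20 deg.
  The apparent contradiction (Moving while the 4-s mean velocity is nearly
  zero) is deliberate: it selects an instantaneous spike inside a long
  quiescent window, exactly the jerk signature.
* ``multi_condition_2`` — center acceleration <= 180 cm/s^2 AND Moving
  (2.00/1.75 cm/s) simultaneously for center, nose and tail-base.

Mobility in the commercial system is pixel-change based.  Without pixels we
use a documented surrogate built from point displacements and posture change
(see :func:`mobility_raw`); when rendered video is available the tracker
module supplies a pixel-change mobility instead, and every consumer accepts
either source.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import yaml

from .core_io import Signal, TrackingSeries
from .kinematics import compute_acceleration, compute_velocity, sliding_average


class Mobility(IntEnum):
    IMMOBILE = 0
    MOBILE = 1
    HIGHLY_MOBILE = 2


MOBILITY_NAMES = {m: m.name.title().replace("_", "") for m in Mobility}


@dataclass
class DetectionConfig:
    """Every numeric threshold of the detection pipeline.

    The movement, multi-condition and mobility thresholds are the published
    analysis-profile settings; the burst/window/pairing parameters
    operationalize the qualitative event criteria ("short (~1 s) burst of
    20-60 cm/s preceded by a long immobile state", consecutive events
    "1-20 s apart", "only the three last hours").  Sample-count windows are
    relative to the acquisition rate (100 samples = 4 s at 25 Hz).
    """

    # Movement hysteresis (cm/s): enter Moving above start, leave below stop.
    move_start_cms: float = 3.20
    move_stop_cms: float = 2.25
    # Multi Condition 1
    mc1_avg_window_samples: int = 100
    mc1_avg_vel_max_cms: float = 0.45
    mc1_elong_max_pct: float = 75.00
    mc1_angle_max_deg: float = 20.00
    # Multi Condition 2
    mc2_accel_max_cms2: float = 180.00
    mc2_move_start_cms: float = 2.00
    mc2_move_stop_cms: float = 1.75
    # Mobility state
    mobility_window_samples: int = 15
    mobility_high_pct: float = 60.00
    mobility_immobile_pct: float = 5.00
    # Burst / event criteria
    burst_vel_min_cms: float = 20.0
    burst_vel_max_cms: float = 60.0
    burst_max_dur_s: float = 1.5
    pre_immobile_min_s: float = 10.0
    pre_immobile_gap_max_s: float = 1.0
    merge_gap_s: float = 1.0
    mc_pad_s: float = 0.2
    # Consecutive-event pairing
    pair_min_gap_s: float = 1.0
    pair_max_gap_s: float = 20.0
    # Analysis window: first hour discarded, last three hours scored.
    analysis_start_s: float = 3600.0
    analysis_end_s: float = 14400.0
    start_latency_s: float = 3.0
    # Voluntary-movement rejection (automated stand-in for visual review)
    walkin_window_s: float = 5.0
    walkin_mobile_frac: float = 0.5
    locomotion_net_disp_cm: float = 10.0
    locomotion_spike_ratio: float = 1.5
    locomotion_lookback_s: float = 10.0
    # Gap handling
    max_gap_s: float = 1.0
    despike: bool = False
    # Mobility surrogate (trajectory-only mode)
    mobility_w_center: float = 0.3
    mobility_w_nose: float = 0.3
    mobility_w_tail: float = 0.3
    mobility_w_elong: float = 0.1
    body_length_cm: float = 7.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.move_stop_cms < self.move_start_cms:
            raise ValueError(
                f"move_stop_cms ({self.move_stop_cms}) must be < "
                f"move_start_cms ({self.move_start_cms})")
        if not self.mc2_move_stop_cms < self.mc2_move_start_cms:
            raise ValueError(
                f"mc2_move_stop_cms ({self.mc2_move_stop_cms}) must be < "
                f"mc2_move_start_cms ({self.mc2_move_start_cms})")
        if not self.mobility_immobile_pct < self.mobility_high_pct:
            raise ValueError("mobility_immobile_pct must be < mobility_high_pct")
        if not self.burst_vel_min_cms < self.burst_vel_max_cms:
            raise ValueError("burst_vel_min_cms must be < burst_vel_max_cms")
        if not self.analysis_start_s < self.analysis_end_s:
            raise ValueError("analysis_start_s must be < analysis_end_s")
        for name in ("mc1_avg_window_samples", "mobility_window_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DetectionConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown detection config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass
class StateSeries:
    """Per-sample state labels aligned to a tracking series.

    ``values`` is boolean for movement / multi-condition states and int8
    :class:`Mobility` codes for the three-level mobility state.
    """

    values: np.ndarray
    kind: str

    def __len__(self) -> int:
        return len(self.values)


def movement_state(
    velocity: Signal | np.ndarray, start_thr_cms: float, stop_thr_cms: float
) -> StateSeries:
    """Hysteretic Moving/Not-moving automaton.

    State turns Moving when velocity exceeds ``start_thr_cms``, Not-moving
    when it drops below ``stop_thr_cms``, and otherwise (including missing
    samples) holds.  Initial state is Not-moving.
    """
    if stop_thr_cms >= start_thr_cms:
        raise ValueError(
            f"stop threshold ({stop_thr_cms}) must be < start threshold "
            f"({start_thr_cms})")
    v = velocity.values if isinstance(velocity, Signal) else np.asarray(velocity, float)
    n = len(v)
    with np.errstate(invalid="ignore"):
        force = np.where(v > start_thr_cms, 1, np.where(v < stop_thr_cms, -1, 0))
    # forward-fill the last forced decision; NaN comparisons are False => hold
    pos = np.where(force != 0, np.arange(n), -1)
    last = np.maximum.accumulate(pos) if n else pos
    state = np.where(last >= 0, force[np.clip(last, 0, None)], -1)
    return StateSeries((state == 1), kind="movement")


def mobility_raw(
    series: TrackingSeries, cfg: DetectionConfig | None = None
) -> Signal:
    """Trajectory-only mobility surrogate, percent of body changed per sample.

    ``100 * min(1, w_c*d_center + w_n*d_nose + w_t*d_tail +
    w_e*|d elongation|/100)`` where ``d_p`` is the per-sample displacement of
    point ``p`` divided by the body-length scale (7 cm by default).  The
    first sample is 0.  This mimics the pixel-change mobility of video-based
    trackers using only the exported trajectory.
    """
    cfg = cfg or DetectionConfig()
    n = len(series)
    terms = np.zeros(n)
    for w, xy in (
        (cfg.mobility_w_center, series.center_xy),
        (cfg.mobility_w_nose, series.nose_xy),
        (cfg.mobility_w_tail, series.tail_xy),
    ):
        d = np.zeros(n)
        if n > 1:
            d[1:] = np.linalg.norm(np.diff(xy, axis=0), axis=1) / cfg.body_length_cm
        terms = terms + w * d
    de = np.zeros(n)
    if n > 1:
        de[1:] = np.abs(np.diff(series.elongation_pct)) / 100.0
    terms = terms + cfg.mobility_w_elong * de
    return Signal(100.0 * np.minimum(1.0, terms), "%", name="mobility")


def mobility_state(mobility: Signal, cfg: DetectionConfig) -> StateSeries:
    """Three-level mobility labels from the smoothed mobility percentage.

    The raw percentage is boxcar-averaged over ``mobility_window_samples``
    and labelled HighlyMobile above ``mobility_high_pct``, Immobile below
    ``mobility_immobile_pct``, Mobile in between.  Missing samples fall in
    the Mobile band (they are neither provably still nor highly mobile).
    """
    m = sliding_average(mobility, cfg.mobility_window_samples)
    vals = m.values if isinstance(m, Signal) else m
    out = np.full(len(vals), Mobility.MOBILE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[vals > cfg.mobility_high_pct] = Mobility.HIGHLY_MOBILE
        out[vals < cfg.mobility_immobile_pct] = Mobility.IMMOBILE
    return StateSeries(out, kind="mobility")


def multi_condition_1(
    series: TrackingSeries,
    cfg: DetectionConfig,
    velocity: Signal | None = None,
) -> StateSeries:
    """Per-sample Multi Condition 1 (all four sub-conditions true)."""
    v = velocity or compute_velocity(series, "center", despike=cfg.despike)
    moving = movement_state(v, cfg.move_start_cms, cfg.move_stop_cms).values
    avg = sliding_average(v, cfg.mc1_avg_window_samples).values
    with np.errstate(invalid="ignore"):
        ok = (
            moving
            & (avg <= cfg.mc1_avg_vel_max_cms)
            & (series.elongation_pct <= cfg.mc1_elong_max_pct)
            & (series.body_angle_deg <= cfg.mc1_angle_max_deg)
        )
    return StateSeries(ok, kind="mc1")


class BodyPointsMissingError(ValueError):
    """Nose/tail-base entirely missing; run trajectory-only (MC2 disabled)."""


def multi_condition_2(
    series: TrackingSeries,
    cfg: DetectionConfig,
    velocity: Signal | None = None,
) -> StateSeries:
    """Per-sample Multi Condition 2.

    Center acceleration magnitude <= ``mc2_accel_max_cms2`` AND the
    hysteretic Moving state (2.00/1.75 cm/s thresholds) simultaneously true
    for center, nose and tail-base.  Raises :class:`BodyPointsMissingError`
    when nose or tail-base were never tracked; callers should then fall back
    to MC1-only detection and flag it in the report.
    """
    for label in ("nose", "tail_base"):
        if np.isnan(series.point(label)).all(axis=None):
            raise BodyPointsMissingError(
                f"{label} point entirely missing: Multi Condition 2 cannot be "
                "evaluated; disable it and run trajectory-only (MC1) detection")
    v_center = velocity or compute_velocity(series, "center", despike=cfg.despike)
    accel = compute_acceleration(v_center, series.sample_rate_hz).values
    ok = np.ones(len(series), dtype=bool)
    with np.errstate(invalid="ignore"):
        ok &= accel <= cfg.mc2_accel_max_cms2
    for label, v in (
        ("center", v_center),
        ("nose", compute_velocity(series, "nose", despike=cfg.despike)),
        ("tail_base", compute_velocity(series, "tail_base", despike=cfg.despike)),
    ):
        ok &= movement_state(v, cfg.mc2_move_start_cms, cfg.mc2_move_stop_cms).values
    return StateSeries(ok, kind="mc2")


@dataclass
class AnalysisProfile:
    """All per-sample signals and states the event detector consumes."""

    series: TrackingSeries            # gap-resolved
    velocity: Signal                  # raw center velocity, cm/s
    acceleration: Signal              # |dv| * rate, cm/s^2
    mobility: Signal                  # %, surrogate or pixel-change
    mobility_states: StateSeries      # Mobility codes
    moving: StateSeries               # 3.20/2.25 hysteresis on center
    mc1: StateSeries
    mc2: StateSeries
    mc2_available: bool
    valid: np.ndarray                 # center resolvable (not missing)

    def __len__(self) -> int:
        return len(self.series)


def compute_profile(
    series: TrackingSeries,
    cfg: DetectionConfig,
    mobility: Signal | None = None,
    resolve_gaps: bool = True,
) -> AnalysisProfile:
    """Build the full analysis profile for one session.

    Short tracking gaps (<= ``cfg.max_gap_s``) are interpolated first;
    longer gaps stay missing and invalidate overlapping candidates.  Pass a
    pixel-change ``mobility`` signal to override the trajectory surrogate.
    """
    from .kinematics import interpolate_gaps

    if resolve_gaps:
        series = interpolate_gaps(series, cfg.max_gap_s)
    v = compute_velocity(series, "center", despike=cfg.despike)
    accel = compute_acceleration(v, series.sample_rate_hz)
    mob = mobility if mobility is not None else mobility_raw(series, cfg)
    mob_states = mobility_state(mob, cfg)
    moving = movement_state(v, cfg.move_start_cms, cfg.move_stop_cms)
    mc1 = multi_condition_1(series, cfg, velocity=v)
    try:
        mc2 = multi_condition_2(series, cfg, velocity=v)
        mc2_available = True
    except BodyPointsMissingError:
        mc2 = StateSeries(np.zeros(len(series), dtype=bool), kind="mc2")
        mc2_available = False
    valid = ~np.isnan(series.center_xy).any(axis=1)
    return AnalysisProfile(
        series=series,
        velocity=v,
        acceleration=accel,
        mobility=mob,
        mobility_states=mob_states,
        moving=moving,
        mc1=mc1,
        mc2=mc2,
        mc2_available=mc2_available,
        valid=valid,
    )


def profile_table(profile: AnalysisProfile):
    """Per-sample audit table (`time_s,moving,mobility_pct,mobility_state,mc1,mc2`)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time_s": profile.series.t,
            "moving": profile.moving.values.astype(int),
            "mobility_pct": profile.mobility.values,
            "mobility_state": [
                MOBILITY_NAMES[Mobility(c)] for c in profile.mobility_states.values
            ],
            "mc1": profile.mc1.values.astype(int),
            "mc2": profile.mc2.values.astype(int),
        }
    )
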