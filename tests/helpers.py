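"""Shared test helpers: series builders and independent brute-force oracles.

The oracles here are deliberately written as literal loops, independent of
the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from myotrack.core_io import TrackingSeries
from myotrack.states import AnalysisProfile, DetectionConfig, Mobility


def make_series(
    center: np.ndarray,
    nose: np.ndarray | None = None,
    tail: np.ndarray | None = None,
    elongation=60.0,
    angle=10.0,
    rate: float = 25.0,
    arena: float = 30.0,
    session_id: str = "test",
) -> TrackingSeries:
    """Build a series from a center path; nose/tail default to +/-2 cm in x."""
    center = np.asarray(center, dtype=float).reshape(-1, 2)
    n = len(center)
    if nose is None:
        nose = center + np.array([2.0, 0.0])
    if tail is None:
        tail = center - np.array([2.0, 0.0])
    return TrackingSeries(
        session_id=session_id,
        sample_rate_hz=rate,
        t=np.arange(n) / rate,
        center_xy=center,
        nose_xy=np.asarray(nose, float).reshape(-1, 2),
        tail_xy=np.asarray(tail, float).reshape(-1, 2),
        elongation_pct=np.broadcast_to(np.asarray(elongation, float), (n,)).copy(),
        body_angle_deg=np.broadcast_to(np.asarray(angle, float), (n,)).copy(),
        arena_w_cm=arena,
        arena_h_cm=arena,
    )


def stationary_center(n: int, xy=(15.0, 15.0)) -> np.ndarray:
    return np.tile(np.asarray(xy, float), (n, 1))


def add_pulse(center: np.ndarray, onset_idx: int, peak_cms: float,
              duration_s: float, rate: float = 25.0, direction=(1.0, 0.0)) -> np.ndarray:
    """Add a half-cosine displacement pulse (peak velocity = peak_cms)."""
    out = center.copy()
    disp = 2.0 * duration_s * peak_cms / math.pi
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    n = len(out)
    m = int(round(duration_s * rate))
    for k in range(onset_idx, n):
        tau = (k - onset_idx) / rate
        g = 1.0 if tau >= duration_s else 0.5 * (1.0 - math.cos(math.pi * tau / duration_s))
        out[k] += disp * g * u
    return out


def walking_center(n: int, speed_cms: float, rate: float = 25.0,
                   start=(6.0, 15.0)) -> np.ndarray:
    """Straight-ish walk bouncing between x=6 and x=24 cm."""
    pos = np.zeros((n, 2))
    x, y = start
    vx = speed_cms / rate
    for i in range(n):
        pos[i] = (x, y)
        x += vx
        if x > 24.0 or x < 6.0:
            vx = -vx
            x += 2 * vx
    return pos


def random_event_rich_series(rng: np.random.Generator, n: int = 4000,
                             rate: float = 25.0) -> TrackingSeries:
    """Randomized series mixing quiescence, bursts, walking and gaps.

    Designed to exercise every candidate criterion: burst peaks straddle the
    20-60 cm/s band, durations straddle the 1.5 s limit, pre-burst immobile
    stretches straddle 10 s, and occasional dropouts create missing spans.
    """
    center = np.tile(rng.uniform(8, 22, size=2), (n, 1))
    # correlated micro-jitter background (sleep-like)
    for d in range(2):
        eps = rng.normal(0, 0.02, size=n)
        for i in range(1, n):
            eps[i] += 0.9 * eps[i - 1]
        center[:, d] += eps
    i = int(rng.integers(0, 200))
    while i < n - 10:
        kind = rng.choice(["burst", "walk", "quiet"], p=[0.35, 0.2, 0.45])
        if kind == "burst":
            dur = float(rng.uniform(0.08, 2.5))
            peak = float(rng.uniform(10.0, 80.0))
            center = add_pulse(center, i, peak, dur, rate,
                               direction=rng.normal(size=2) + 1e-6)
            i += int(dur * rate) + int(rng.integers(5, 30))
        elif kind == "walk":
            m = int(rng.uniform(2.0, 8.0) * rate)
            speed = float(rng.uniform(5.0, 18.0))
            phi = float(rng.uniform(0, 2 * np.pi))
            step = speed / rate * np.array([np.cos(phi), np.sin(phi)])
            for k in range(i, min(i + m, n)):
                center[k:] += step  # translate the remainder: continuous walk
            i += m + int(rng.integers(5, 30))
        else:
            i += int(rng.uniform(2.0, 20.0) * rate)
    center = np.clip(center, 0.5, 29.5)
    nose = center + np.array([2.0, 0.0])
    tail = center - np.array([2.0, 0.0])
    elong = np.clip(60 + np.cumsum(rng.normal(0, 0.3, n)), 0, 100)
    angle = np.clip(10 + np.cumsum(rng.normal(0, 0.2, n)), 0, 180)
    series = make_series(center, nose, tail, elong, angle, rate=rate)
    # sprinkle dropouts (some spans longer than the interpolation limit)
    for _ in range(int(rng.integers(0, 4))):
        j = int(rng.integers(0, n - 60))
        span = int(rng.integers(1, 50))
        for arr in (series.center_xy, series.nose_xy, series.tail_xy):
            arr[j:j + span] = np.nan
        series.elongation_pct[j:j + span] = np.nan
        series.body_angle_deg[j:j + span] = np.nan
    series.missing = series._nan_mask()
    return series


# ---------------------------------------------------------------------------
# literal-loop oracles

def boxcar_oracle(values: np.ndarray, window: int) -> np.ndarray:
    """Centered truncated NaN-excluding boxcar mean, as an explicit loop."""
    n = len(values)
    left = (window - 1) // 2
    right = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        chunk = [v for v in values[lo:hi] if np.isfinite(v)]
        if chunk:
            out[i] = sum(chunk) / len(chunk)
    return out


def hysteresis_oracle(v: np.ndarray, start: float, stop: float) -> np.ndarray:
    """Hand-stepped two-state automaton."""
    state = False
    out = np.zeros(len(v), dtype=bool)
    for i, x in enumerate(v):
        if np.isfinite(x):
            if x > start:
                state = True
            elif x < stop:
                state = False
        out[i] = state
    return out


def mobility_oracle(series: TrackingSeries, cfg: DetectionConfig) -> np.ndarray:
    """Literal evaluation of the trajectory mobility surrogate."""
    n = len(series)
    out = np.zeros(n)
    for i in range(1, n):
        total = 0.0
        for w, xy in ((cfg.mobility_w_center, series.center_xy),
                      (cfg.mobility_w_nose, series.nose_xy),
                      (cfg.mobility_w_tail, series.tail_xy)):
            dx = xy[i, 0] - xy[i - 1, 0]
            dy = xy[i, 1] - xy[i - 1, 1]
            total += w * math.sqrt(dx * dx + dy * dy) / cfg.body_length_cm
        total += cfg.mobility_w_elong * abs(
            series.elongation_pct[i] - series.elongation_pct[i - 1]) / 100.0
        out[i] = 100.0 * min(1.0, total)
    return out


def candidates_oracle(profile: AnalysisProfile, cfg: DetectionConfig) -> list[dict]:
    """Exhaustive brute-force candidate scan applying the burst criteria
    (run shape, peak band, pre-immobility, multi-condition hit) literally."""
    ser = profile.series
    t = ser.t
    v = profile.velocity.values
    n = len(ser)
    dt = ser.dt
    codes = profile.mobility_states.values

    above = []
    for i in range(n):
        x = v[i]
        above.append(bool(np.isfinite(x) and x > cfg.burst_vel_min_cms
                          and cfg.analysis_start_s <= t[i] <= cfg.analysis_end_s))
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for r in runs:
        if merged and t[r[0]] - t[merged[-1][1]] < cfg.merge_gap_s:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    pad = int(round(cfg.mc_pad_s * ser.sample_rate_hz))
    out = []
    for s, e in merged:  # e inclusive
        dur = (e - s + 1) * dt
        if dur > cfg.burst_max_dur_s:
            continue
        peak = np.nanmax(v[s:e + 1])
        if not (cfg.burst_vel_min_cms <= peak <= cfg.burst_vel_max_cms):
            continue
        # immobile run immediately before onset
        k = s - 1
        while k >= 0 and codes[k] != Mobility.IMMOBILE:
            k -= 1
        pre = 0.0
        if k >= 0:
            gap = (s - (k + 1)) * dt
            if gap <= cfg.pre_immobile_gap_max_s:
                m = k
                while m >= 0 and codes[m] == Mobility.IMMOBILE:
                    m -= 1
                pre = (k - m) * dt
        if pre < cfg.pre_immobile_min_s:
            continue
        lo = max(0, s - pad)
        hi = min(n, e + 1 + pad)
        hit1 = any(bool(x) for x in profile.mc1.values[lo:hi])
        hit2 = any(bool(x) for x in profile.mc2.values[lo:hi])
        if not (hit1 or hit2):
            continue
        out.append({"onset_idx": s, "offset_idx": e, "peak": float(peak),
                    "pre_immobile_s": pre, "mc1": hit1, "mc2": hit2})
    return out


def anova_ss_oracle(values: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict:
    """Closed-form sums-of-squares two-way ANOVA for balanced designs."""
    a_levels = sorted(set(a))
    b_levels = sorted(set(b))
    I, J = len(a_levels), len(b_levels)
    cell = {}
    for ai in a_levels:
        for bj in b_levels:
            cell[(ai, bj)] = values[(a == ai) & (b == bj)]
    K = len(next(iter(cell.values())))
    assert all(len(v) == K for v in cell.values()), "oracle needs balance"
    grand = values.mean()
    mean_a = {ai: values[a == ai].mean() for ai in a_levels}
    mean_b = {bj: values[b == bj].mean() for bj in b_levels}
    ss_a = J * K * sum((mean_a[ai] - grand) ** 2 for ai in a_levels)
    ss_b = I * K * sum((mean_b[bj] - grand) ** 2 for bj in b_levels)
    ss_ab = K * sum(
        (cell[(ai, bj)].mean() - mean_a[ai] - mean_b[bj] + grand) ** 2
        for ai in a_levels for bj in b_levels)
    ss_e = sum(((cell[(ai, bj)] - cell[(ai, bj)].mean()) ** 2).sum()
               for ai in a_levels for bj in b_levels)
    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_e = I * J * (K - 1)
    mse = ss_e / df_e
    return {
        "f_a": (ss_a / df_a) / mse,
        "f_b": (ss_b / df_b) / mse,
        "f_ab": (ss_ab / df_ab) / mse,
        "df": (df_a, df_b, df_ab, df_e),
    }
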