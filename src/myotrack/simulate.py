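"""Ground-truth home-cage behavior simulator.

Synthesizes 4-h recording sessions of a single mouse in a 30x30 cm arena as
a semi-Markov chain of behavioral bouts with exponential holding times:

* ``explore`` — smooth correlated random walk at 5-15 cm/s, stretched
  posture; biased to dominate the first hour (animals explore a fresh cage
  before settling).
* ``sleep`` — stationary curled posture with sub-threshold jitter only.
* ``groom`` — in-place small oscillations of position and posture.

Myoclonic jerks are injected at Poisson times within sleep bouts as
half-cosine displacement pulses in a (wall-aware) random direction, with the
pulse magnitude chosen so the peak velocity hits a sampled target in the
20-60 cm/s band.  A jerk may spawn a partner event 1-20 s later, emulating
the consecutive-event phenomenon.  Tracking imperfections are applied last:
temporally correlated (AR(1)) centroid jitter — white jitter at video rate
would alias into cm/s-scale velocity noise no real tracker produces — and
random dropout samples.

Behavior and noise use independent seeded streams, so re-simulating with the
same seed but zero noise yields bit-identical ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .core_io import TrackingSeries

#: Rendered/assumed body area (cm^2) used to derive ellipse axes from the
#: elongation descriptor: ratio r = 1 - elongation/100, a = sqrt(A/(pi r)).
BODY_AREA_CM2 = 13.7
#: Body points sit at 85% of the semi-major axis from the centroid.
POINT_FRAC = 0.85
#: Semi-major axis cap (cm): even a fully stretched mouse body stays ~10 cm
#: long.  Together with the walk margin this keeps the whole body inside the
#: arena, so rendered blobs are never truncated at the walls.
MAX_SEMI_AXIS_CM = 5.0
#: Distance (cm) the center keeps from the walls while walking/jerking.
WALL_MARGIN_CM = 5.0
#: AR(1) coefficient of the tracking jitter (per sample at 25 Hz).
NOISE_RHO = 0.9
#: Jerks are only injected this long (s) after sleep-bout onset (sleep-onset
#: latency) and this long before bout end.
JERK_LEAD_IN_S = 15.0
JERK_LEAD_OUT_S = 3.0
#: Minimum separation (s) between primary injected jerks.
JERK_MIN_SEP_S = 25.0


@dataclass
class SimulationConfig:
    """All simulator parameters (defaults emulate the study conditions)."""

    duration_s: float = 14400.0
    sample_rate_hz: float = 25.0
    arena_cm: tuple[float, float] = (30.0, 30.0)
    seed: int = 0
    explore_bout_mean_s: float = 60.0
    sleep_bout_mean_s: float = 600.0
    groom_bout_mean_s: float = 30.0
    initial_explore_s: float = 3600.0
    jerk_rate_per_h: float = 4.0
    jerk_peak_cms_range: tuple[float, float] = (25.0, 55.0)
    jerk_dur_s_range: tuple[float, float] = (0.2, 0.8)
    pair_prob: float = 0.15
    walk_speed_cms_range: tuple[float, float] = (5.0, 15.0)
    tracking_noise_sd_cm: float = 0.05
    dropout_prob_per_sample: float = 0.001
    session_id: str = "sim"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.jerk_rate_per_h < 0:
            raise ValueError("jerk_rate_per_h must be >= 0")
        if not (0.0 <= self.pair_prob <= 1.0):
            raise ValueError("pair_prob must be in [0, 1]")
        if not (0.0 <= self.dropout_prob_per_sample <= 1.0):
            raise ValueError("dropout_prob_per_sample must be in [0, 1]")
        for name in ("jerk_peak_cms_range", "jerk_dur_s_range", "walk_speed_cms_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered (lo, hi) pair")
        if self.jerk_dur_s_range[1] + JERK_LEAD_IN_S + JERK_LEAD_OUT_S >= \
                10.0 * self.sleep_bout_mean_s:
            raise ValueError("jerk duration incompatible with sleep bout scale")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("arena_cm", "jerk_peak_cms_range", "jerk_dur_s_range",
                  "walk_speed_cms_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        for k in ("arena_cm", "jerk_peak_cms_range", "jerk_dur_s_range",
                  "walk_speed_cms_range"):
            if k in data:
                data[k] = tuple(data[k])
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class JerkTruth:
    time_s: float          # pulse onset
    peak_cms: float        # target peak velocity
    duration_s: float
    pair_id: int | None = None


@dataclass
class GroundTruth:
    """Injected-jerk annotations and the bout schedule (acceptance oracle)."""

    jerks: list[JerkTruth] = field(default_factory=list)
    bouts: list[tuple[float, float, str]] = field(default_factory=list)

    def jerk_times(self, start_s: float = -math.inf, end_s: float = math.inf) -> np.ndarray:
        return np.array([j.time_s for j in self.jerks if start_s <= j.time_s <= end_s])

    def to_json(self, path) -> str:
        payload = {
            "jerks": [dataclasses.asdict(j) for j in self.jerks],
            "bouts": [list(b) for b in self.bouts],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
        return str(path)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            jerks=[JerkTruth(**j) for j in payload["jerks"]],
            bouts=[(b[0], b[1], b[2]) for b in payload["bouts"]],
        )


# Bout-label transition probabilities: a fresh cage is explored, later the
# animal mostly sleeps.
_PHASE1_PROBS = {"explore": 0.60, "groom": 0.25, "sleep": 0.15}
_PHASE2_PROBS = {"explore": 0.15, "groom": 0.15, "sleep": 0.70}
_LABELS = ("explore", "sleep", "groom")


def _draw_bouts(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[float, float, str]]:
    means = {
        "explore": cfg.explore_bout_mean_s,
        "sleep": cfg.sleep_bout_mean_s,
        "groom": cfg.groom_bout_mean_s,
    }
    bouts: list[tuple[float, float, str]] = []
    t = 0.0
    label = "explore"  # the animal was just placed into the cage
    while t < cfg.duration_s:
        dur = max(2.0, rng.exponential(means[label]))
        end = min(t + dur, cfg.duration_s)
        bouts.append((t, end, label))
        t = end
        probs = _PHASE1_PROBS if t < cfg.initial_explore_s else _PHASE2_PROBS
        label = str(rng.choice(_LABELS, p=[probs[l] for l in _LABELS]))
    return bouts


def _jerk_direction(
    pos: np.ndarray, disp: float, arena: tuple[float, float],
    rng: np.random.Generator, margin: float = WALL_MARGIN_CM,
) -> tuple[np.ndarray, float]:
    """Unit direction (and possibly shortened displacement) staying in-arena."""
    w, h = arena
    for _ in range(50):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(phi), np.sin(phi)])
        end = pos + disp * u
        if margin <= end[0] <= w - margin and margin <= end[1] <= h - margin:
            return u, disp
    center = np.array([w / 2.0, h / 2.0])
    u = center - pos
    nrm = np.linalg.norm(u)
    u = u / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
    # clamp the displacement to the clearance along the center direction
    lo = 0.0
    hi = disp
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        end = pos + mid * u
        if margin <= end[0] <= w - margin and margin <= end[1] <= h - margin:
            lo = mid
        else:
            hi = mid
    return u, max(lo, 0.5)


def _draw_jerks(
    cfg: SimulationConfig,
    bouts: list[tuple[float, float, str]],
    rng: np.random.Generator,
) -> list[JerkTruth]:
    jerks: list[JerkTruth] = []
    pair_counter = 0
    for start, end, label in bouts:
        if label != "sleep":
            continue
        lo = start + JERK_LEAD_IN_S
        hi = end - JERK_LEAD_OUT_S - cfg.jerk_dur_s_range[1]
        if hi <= lo or cfg.jerk_rate_per_h == 0:
            continue
        n = rng.poisson(cfg.jerk_rate_per_h * (hi - lo) / 3600.0)
        times = np.sort(rng.uniform(lo, hi, size=n))
        kept: list[float] = []
        for tj in times:
            if not kept or tj - kept[-1] >= JERK_MIN_SEP_S:
                kept.append(float(tj))
        for tj in kept:
            peak = float(rng.uniform(*cfg.jerk_peak_cms_range))
            dur = float(rng.uniform(*cfg.jerk_dur_s_range))
            primary = JerkTruth(tj, peak, dur)
            jerks.append(primary)
            if rng.uniform() < cfg.pair_prob:
                gap = float(rng.uniform(1.0, 20.0))
                tp = tj + dur + gap
                p_dur = float(rng.uniform(*cfg.jerk_dur_s_range))
                if tp + p_dur < hi and (tj + JERK_MIN_SEP_S) > tp:
                    primary.pair_id = pair_counter
                    jerks.append(JerkTruth(tp, float(rng.uniform(*cfg.jerk_peak_cms_range)),
                                           p_dur, pair_id=pair_counter))
                    pair_counter += 1
    jerks.sort(key=lambda j: j.time_s)
    # drop overlaps across bout boundaries (cannot happen within a bout)
    out: list[JerkTruth] = []
    for j in jerks:
        if out and j.time_s < out[-1].time_s + out[-1].duration_s + 0.5:
            continue
        out.append(j)
    return out


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float = NOISE_RHO) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    eps = rng.standard_normal(n) * sd * math.sqrt(1.0 - rho * rho)
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -rho], eps)


def _axis_from_elongation(elongation_pct: np.ndarray) -> np.ndarray:
    """Semi-major axis length (cm) for a constant-area body ellipse."""
    r = np.maximum(0.05, 1.0 - np.asarray(elongation_pct, float) / 100.0)
    return np.minimum(MAX_SEMI_AXIS_CM, np.sqrt(BODY_AREA_CM2 / (np.pi * r)))


def simulate_session(cfg: SimulationConfig) -> tuple[TrackingSeries, GroundTruth]:
    """Simulate one session; seeded and bit-reproducible."""
    rate = cfg.sample_rate_hz
    dt = 1.0 / rate
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) * dt
    w, h = cfg.arena_cm
    rng_b = np.random.default_rng([cfg.seed, 11])   # behavior
    rng_n = np.random.default_rng([cfg.seed, 13])   # measurement noise

    bouts = _draw_bouts(cfg, rng_b)
    jerks = _draw_jerks(cfg, bouts, rng_b)

    pos = np.zeros((n, 2))
    heading = np.zeros((n, 2))
    elong = np.zeros(n)
    angle = np.zeros(n)

    cur_pos = np.array([w / 2.0, h / 2.0]) + rng_b.uniform(-3, 3, size=2)
    cur_theta = rng_b.uniform(0, 2 * np.pi)
    lo_v, hi_v = cfg.walk_speed_cms_range
    margin = WALL_MARGIN_CM

    for start, end, label in bouts:
        i0 = int(round(start * rate))
        i1 = min(int(round(end * rate)), n)
        if i1 <= i0:
            continue
        m = i1 - i0
        if label == "explore":
            z = rng_b.standard_normal()  # slow speed modulation state
            dthetas = rng_b.standard_normal(m) * 0.12
            zsteps = rng_b.standard_normal(m)
            e_base = rng_b.uniform(85.0, 95.0)
            a_base = rng_b.uniform(5.0, 25.0)
            p = cur_pos.copy()
            th = cur_theta
            for k in range(m):
                th += dthetas[k]
                z = 0.99 * z + 0.14 * zsteps[k]
                speed = lo_v + (hi_v - lo_v) / (1.0 + math.exp(-z))
                step = speed * dt
                nx = p[0] + step * math.cos(th)
                ny = p[1] + step * math.sin(th)
                if nx < margin or nx > w - margin:
                    th = math.pi - th
                    nx = min(max(nx, margin), w - margin)
                if ny < margin or ny > h - margin:
                    th = -th
                    ny = min(max(ny, margin), h - margin)
                p[0], p[1] = nx, ny
                pos[i0 + k] = p
                heading[i0 + k] = (math.cos(th), math.sin(th))
            cur_pos = p.copy()
            cur_theta = th
            tau = np.arange(m) * dt
            elong[i0:i1] = np.clip(
                e_base + 2.0 * np.sin(2 * np.pi * 0.2 * tau), 0, 100)
            angle[i0:i1] = np.clip(
                a_base + 8.0 * np.sin(2 * np.pi * 0.3 * tau + 1.0), 0, 180)
        elif label == "sleep":
            base = cur_pos.copy()
            e_base = rng_b.uniform(55.0, 70.0)
            a_base = rng_b.uniform(5.0, 15.0)
            tau = np.arange(m) * dt
            seg = np.tile(base, (m, 1))
            # injected jerk pulses: permanent displacement ramped by a
            # half-cosine, so peak velocity == target peak
            for j in jerks:
                if not (start <= j.time_s < end):
                    continue
                disp = 2.0 * j.duration_s * j.peak_cms / math.pi
                u, disp2 = _jerk_direction(base, disp, cfg.arena_cm, rng_b)
                if disp2 < disp:
                    # wall clamp: shorten the pulse to preserve peak velocity
                    j.duration_s = max(0.12, math.pi * disp2 / (2.0 * j.peak_cms))
                    j.peak_cms = math.pi * disp2 / (2.0 * j.duration_s)
                disp = disp2
                rel = t[i0:i1] - j.time_s
                g = np.clip(rel / j.duration_s, 0.0, 1.0)
                g = 0.5 * (1.0 - np.cos(np.pi * g))
                g[rel < 0] = 0.0
                seg = seg + disp * np.outer(g, u)
                base = base + disp * u  # subsequent jerks start displaced
            pos[i0:i1] = seg
            heading[i0:i1] = (math.cos(cur_theta), math.sin(cur_theta))
            elong[i0:i1] = e_base + 0.5 * np.sin(2 * np.pi * 3.0 * tau)  # breathing
            angle[i0:i1] = a_base
            cur_pos = seg[-1].copy()
        else:  # groom
            base = cur_pos.copy()
            e_base = rng_b.uniform(70.0, 85.0)
            a_base = rng_b.uniform(10.0, 25.0)
            f = rng_b.uniform(3.0, 5.0)
            amp = rng_b.uniform(0.35, 0.55)
            phi = rng_b.uniform(0, 2 * np.pi)
            u = np.array([math.cos(phi), math.sin(phi)])
            tau = np.arange(m) * dt
            osc = amp * np.sin(2 * np.pi * f * tau)
            pos[i0:i1] = base + np.outer(osc, u)
            heading[i0:i1] = (math.cos(cur_theta), math.sin(cur_theta))
            elong[i0:i1] = np.clip(e_base + 3.0 * np.sin(2 * np.pi * f * tau), 0, 100)
            angle[i0:i1] = np.clip(a_base + 5.0 * np.sin(2 * np.pi * f * tau), 0, 180)
            cur_pos = pos[i1 - 1].copy()

    # body geometry: nose rotated off the trunk axis by the bend angle
    a_len = _axis_from_elongation(elong)
    beta = np.deg2rad(angle)
    cosb, sinb = np.cos(beta), np.sin(beta)
    hx, hy = heading[:, 0], heading[:, 1]
    nose_dir = np.column_stack([hx * cosb - hy * sinb, hx * sinb + hy * cosb])
    nose = pos + POINT_FRAC * a_len[:, None] * nose_dir
    tail = pos - POINT_FRAC * a_len[:, None] * heading
    for arr in (nose, tail):
        np.clip(arr[:, 0], 0.0, w, out=arr[:, 0])
        np.clip(arr[:, 1], 0.0, h, out=arr[:, 1])

    # measurement noise: correlated jitter on every channel, then dropouts
    center = pos.copy()
    for arr in (center, nose, tail):
        arr[:, 0] = np.clip(arr[:, 0] + _ar1(rng_n, n, cfg.tracking_noise_sd_cm), 0, w)
        arr[:, 1] = np.clip(arr[:, 1] + _ar1(rng_n, n, cfg.tracking_noise_sd_cm), 0, h)
    elong = np.clip(elong + _ar1(rng_n, n, 1.0 if cfg.tracking_noise_sd_cm else 0.0), 0, 100)
    angle = np.clip(angle + _ar1(rng_n, n, 1.0 if cfg.tracking_noise_sd_cm else 0.0), 0, 180)
    drop = rng_n.uniform(size=n) < cfg.dropout_prob_per_sample
    for arr in (center, nose, tail):
        arr[drop] = np.nan
    elong[drop] = np.nan
    angle[drop] = np.nan

    series = TrackingSeries(
        session_id=cfg.session_id,
        sample_rate_hz=rate,
        t=t,
        center_xy=center,
        nose_xy=nose,
        tail_xy=tail,
        elongation_pct=elong,
        body_angle_deg=angle,
        arena_w_cm=w,
        arena_h_cm=h,
    )
    return series, GroundTruth(jerks=jerks, bouts=bouts)


# ---------------------------------------------------------------------------
# frame rendering (lets the blob tracker be tested end to end)

BACKGROUND_LEVEL = 25
BODY_LEVEL = 180
NOSE_LEVEL = 255
NOSE_LOBE_RADIUS_CM = 0.5


def _draw_body(
    frame: np.ndarray,
    center_px: np.ndarray,
    axis_dir: np.ndarray,
    a_px: float,
    b_px: float,
    nose_px: np.ndarray,
    lobe_r_px: float,
) -> None:
    """Rasterize body ellipse + brighter nose lobe into ``frame`` (in place)."""
    hgt, wid = frame.shape
    # ellipse: local bounding box, exact implicit equation
    ext = int(math.ceil(a_px)) + 1
    r0 = max(0, int(center_px[1]) - ext)
    r1 = min(hgt, int(center_px[1]) + ext + 1)
    c0 = max(0, int(center_px[0]) - ext)
    c1 = min(wid, int(center_px[0]) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - center_px[0]
    dy = rr - center_px[1]
    along = dx * axis_dir[0] + dy * axis_dir[1]
    across = -dx * axis_dir[1] + dy * axis_dir[0]
    mask = (along / a_px) ** 2 + (across / b_px) ** 2 <= 1.0
    frame[r0:r1, c0:c1][mask] = BODY_LEVEL
    # nose lobe
    ext = int(math.ceil(lobe_r_px)) + 1
    r0 = max(0, int(nose_px[1]) - ext)
    r1 = min(hgt, int(nose_px[1]) + ext + 1)
    c0 = max(0, int(nose_px[0]) - ext)
    c1 = min(wid, int(nose_px[0]) + ext + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask = (cc - nose_px[0]) ** 2 + (rr - nose_px[1]) ** 2 <= lobe_r_px ** 2
    frame[r0:r1, c0:c1][mask] = NOSE_LEVEL


def render_frames(
    series: TrackingSeries,
    px_per_cm: float,
    out: str | None = None,
) -> np.ndarray | str:
    """Render one 8-bit grayscale frame per sample.

    Dark background; the body is a bright filled ellipse whose center,
    orientation and axis ratio encode the center point, trunk axis and
    elongation; the nose is a brighter terminal lobe at the nose point so a
    tracker can orient head vs tail.  Missing samples render as background
    only.  ``out`` may be ``None`` (return the ``(n, H, W)`` stack), a
    ``.tif``/``.tiff`` path (multi-page TIFF) or a directory (PNG files).
    """
    hgt = int(round(series.arena_h_cm * px_per_cm))
    wid = int(round(series.arena_w_cm * px_per_cm))
    n = len(series)
    frames = np.full((n, hgt, wid), BACKGROUND_LEVEL, dtype=np.uint8)
    a_len = _axis_from_elongation(np.nan_to_num(series.elongation_pct, nan=60.0))
    b_len = BODY_AREA_CM2 / (np.pi * a_len)
    lobe_r_px = NOSE_LOBE_RADIUS_CM * px_per_cm
    for i in range(n):
        c = series.center_xy[i]
        nose = series.nose_xy[i]
        tail = series.tail_xy[i]
        if np.isnan(c).any() or np.isnan(nose).any() or np.isnan(tail).any():
            continue
        axis = c - tail
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
        _draw_body(
            frames[i], c * px_per_cm, axis,
            a_len[i] * px_per_cm, b_len[i] * px_per_cm,
            nose * px_per_cm, lobe_r_px,
        )
    if out is None:
        return frames
    out = str(out)
    if out.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(out, frames)
        return out
    import os

    import imageio.v3 as iio

    os.makedirs(out, exist_ok=True)
    for i in range(n):
        iio.imwrite(os.path.join(out, f"frame_{i:06d}.png"), frames[i])
    return out
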