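"""Minimal overhead-view blob tracker.

Turns grayscale frame stacks (rendered by :mod:`myotrack.simulate`, or any
high-contrast overhead recording of a single animal) into a
:class:`~myotrack.core_io.TrackingSeries`:

* background: per-pixel median over a uniform frame subsample;
* segmentation: Otsu threshold on the |frame - background| difference image,
  keep the largest 8-connected component;
* body points: mask centroid (center), the brighter terminal lobe (nose),
  and the far principal-axis endpoint pulled 15% toward the centroid
  (tail-base);
* descriptors: elongation = 100*(1 - minor/major axis ratio), so a circle
  scores 0 and a stretched body approaches 100; body angle = deviation of
  the nose/center/tail triplet from collinearity (0 deg = straight body);
* mobility: pixel-change fraction between consecutive body masks
  (XOR / union, x100) — the pixel-faithful alternative to the trajectory
  surrogate in :mod:`myotrack.states`.

Head/tail identity uses the nose lobe's brightness; when the lobe is not
distinguishable the orientation is carried over from the previous frame by
nearest-neighbor continuity.
"""

from __future__ import annotations

import glob
import math
import os
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core_io import Signal, TrackingSeries

#: Fraction of the principal-axis half-length at which the tail-base sits.
TAIL_PULL_FRAC = 0.85


def load_frames(src) -> np.ndarray:
    """Load a frame stack from an ndarray, a multi-page TIFF or a PNG directory."""
    if isinstance(src, np.ndarray):
        return src
    path = str(src)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path)
    if os.path.isdir(path):
        import imageio.v3 as iio

        files = sorted(glob.glob(os.path.join(path, "*.png")))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([iio.imread(f) for f in files])
    raise ValueError(f"unsupported frame source: {src!r}")


def estimate_background(frames: np.ndarray, max_frames: int = 200) -> np.ndarray:
    """Per-pixel median over a uniform subsample of at most ``max_frames``.

    The animal occupies any given pixel in a minority of frames, so the
    median recovers the empty arena.  Requires at least 10 frames.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 10:
        raise ValueError(f"need a stack of >= 10 frames, got shape {frames.shape}")
    idx = np.unique(np.linspace(0, len(frames) - 1, min(max_frames, len(frames))).astype(int))
    return np.median(frames[idx], axis=0).astype(frames.dtype)


def segment_frame(
    frame: np.ndarray, background: np.ndarray, thr: float | None = None
) -> np.ndarray:
    """Binary body mask: largest 8-connected component above threshold.

    ``thr`` defaults to Otsu's threshold on the absolute difference image; a
    fixed gray-level override is available for degenerate illumination.
    Returns an all-false mask when nothing exceeds the threshold.
    """
    if frame.shape != background.shape:
        raise ValueError(f"frame shape {frame.shape} != background shape {background.shape}")
    diff = np.abs(frame.astype(np.int16) - background.astype(np.int16))
    if thr is None:
        if diff.max() == 0:
            return np.zeros(frame.shape, dtype=bool)
        thr = threshold_otsu(diff)
    fg = diff > thr
    if not fg.any():
        return np.zeros(frame.shape, dtype=bool)
    lab = label(fg, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


@dataclass
class BodyPoints:
    center_xy: tuple[float, float]
    nose_xy: tuple[float, float]
    tail_xy: tuple[float, float]
    elongation_pct: float
    body_angle_deg: float


def extract_body_points(
    mask: np.ndarray,
    intensity: np.ndarray,
    px_per_cm: float,
    prev_nose_xy: tuple[float, float] | None = None,
) -> BodyPoints:
    """Body landmarks and posture descriptors from one segmented frame.

    Raises ``ValueError`` on an empty mask (caller records a missing sample).
    ``prev_nose_xy`` (cm) resolves head/tail orientation when no brighter
    nose lobe is visible.
    """
    if not mask.any():
        raise ValueError("empty mask")
    # The nose is marked by a brighter terminal lobe; body geometry (centroid,
    # principal axis, elongation) is measured on the body pixels only so the
    # marker does not bias the centroid or rotate the axis.
    body_vals = intensity[mask]
    body_median = float(np.median(body_vals))
    bright = mask & (intensity > (body_median + (intensity.max() - body_median) / 2.0))
    body_mask = mask & ~bright
    if not body_mask.any():
        body_mask = mask
        bright = np.zeros_like(mask)
    props = regionprops(body_mask.astype(np.uint8), intensity_image=intensity)[0]
    cy, cx = props.centroid
    major = props.axis_major_length
    minor = props.axis_minor_length
    elongation = 100.0 * (1.0 - minor / major) if major > 0 else 0.0
    # principal axis direction in (x, y) image coordinates
    ori = props.orientation  # angle between row-axis and major axis
    axis = np.array([math.sin(ori), math.cos(ori)])
    half = major / 2.0
    center = np.array([cx, cy])
    ends = [center + s * half * axis for s in (+1.0, -1.0)]
    if bright.any():
        # nose = lobe centroid (the marked nose point, possibly off-axis when
        # the body is bent); tail end = the principal-axis end farther from it
        rr, cc = np.nonzero(bright)
        nose_end = np.array([cc.mean(), rr.mean()])
        tail_end = max(ends, key=lambda e: float(np.linalg.norm(e - nose_end)))
    else:
        # no lobe visible: orient head/tail by continuity with the last frame
        if prev_nose_xy is not None:
            prev = np.array(prev_nose_xy) * px_per_cm
            nose_end = min(ends, key=lambda e: float(np.linalg.norm(e - prev)))
        else:
            nose_end = ends[0]
        tail_end = ends[1] if nose_end is ends[0] else ends[0]
    tail = center + TAIL_PULL_FRAC * (tail_end - center)
    v1 = nose_end - center
    v2 = tail - center
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 > 1e-9 and n2 > 1e-9:
        cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
        body_angle = 180.0 - math.degrees(math.acos(cosang))
    else:
        body_angle = 0.0
    s = 1.0 / px_per_cm
    return BodyPoints(
        center_xy=(cx * s, cy * s),
        nose_xy=(float(nose_end[0]) * s, float(nose_end[1]) * s),
        tail_xy=(float(tail[0]) * s, float(tail[1]) * s),
        elongation_pct=float(np.clip(elongation, 0.0, 100.0)),
        body_angle_deg=float(np.clip(body_angle, 0.0, 180.0)),
    )


def track_video(
    frames,
    px_per_cm: float,
    sample_rate_hz: float,
    session_id: str = "tracked",
    thr: float | None = None,
) -> tuple[TrackingSeries, Signal]:
    """Track a frame stack; returns the series and a pixel-change mobility signal.

    Frames that fail segmentation become missing samples (logged, not
    fatal).  Mobility is ``100 * |mask XOR prev_mask| / |mask OR prev_mask|``
    between consecutive frames (0 for the first frame and wherever either
    mask is empty-vs-empty).
    """
    stack = load_frames(frames)
    n = len(stack)
    bg = estimate_background(stack)
    center = np.full((n, 2), np.nan)
    nose = np.full((n, 2), np.nan)
    tail = np.full((n, 2), np.nan)
    elong = np.full(n, np.nan)
    angle = np.full(n, np.nan)
    mobility = np.zeros(n)
    prev_mask: np.ndarray | None = None
    prev_nose: tuple[float, float] | None = None
    for i in range(n):
        mask = segment_frame(stack[i], bg, thr=thr)
        if prev_mask is not None:
            union = int((mask | prev_mask).sum())
            if union:
                mobility[i] = 100.0 * int((mask ^ prev_mask).sum()) / union
        prev_mask = mask
        try:
            bp = extract_body_points(mask, stack[i], px_per_cm, prev_nose_xy=prev_nose)
        except ValueError:
            continue
        center[i] = bp.center_xy
        nose[i] = bp.nose_xy
        tail[i] = bp.tail_xy
        elong[i] = bp.elongation_pct
        angle[i] = bp.body_angle_deg
        prev_nose = bp.nose_xy
    hgt, wid = stack.shape[1:]
    series = TrackingSeries(
        session_id=session_id,
        sample_rate_hz=sample_rate_hz,
        t=np.arange(n) / sample_rate_hz,
        center_xy=center,
        nose_xy=nose,
        tail_xy=tail,
        elongation_pct=elong,
        body_angle_deg=angle,
        arena_w_cm=wid / px_per_cm,
        arena_h_cm=hgt / px_per_cm,
    )
    return series, Signal(mobility, "%", name="mobility[pixel]")
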