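"""Kinematic signals derived from a tracking session.

Velocity is the Euclidean displacement between consecutive samples scaled by
the sample rate (the "averaging interval 1 sample" raw velocity of the
detection profile), optionally boxcar-smoothed.  Acceleration is the
magnitude of the first difference of velocity scaled by the sample rate,
because the detection profile bounds its magnitude.  All boxcar averages are
centered and truncated at the edges, and exclude missing (NaN) samples; a
window with no finite sample stays missing.

First-sample derivatives are defined as 0 (not missing) so the downstream
state machines have defined input from t=0.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import medfilt

from .core_io import Signal, TrackingSeries

POINT_LABELS = ("center", "nose", "tail_base")


def sliding_average(signal: Signal | np.ndarray, window: int) -> Signal | np.ndarray:
    """Centered boxcar mean over ``window`` samples, truncated at the edges.

    The window at sample ``i`` covers ``[i - (window-1)//2, i + window//2]``
    clipped to the signal; NaN samples are excluded from the mean and an
    all-NaN window yields NaN.  ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    values = signal.values if isinstance(signal, Signal) else np.asarray(signal, float)
    out = _nan_boxcar(values, window)
    if isinstance(signal, Signal):
        return Signal(out, signal.unit, name=f"{signal.name}|avg{window}")
    return out


def _nan_boxcar(values: np.ndarray, window: int) -> np.ndarray:
    n = len(values)
    if n == 0 or window == 1:
        return values.copy()
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(finite.astype(np.int64))))
    left = (window - 1) // 2
    right = window // 2
    idx = np.arange(n)
    lo = np.clip(idx - left, 0, n)
    hi = np.clip(idx + right + 1, 0, n)
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out


def compute_velocity(
    series: TrackingSeries,
    point: str = "center",
    averaging_interval: int = 1,
    despike: bool = False,
) -> Signal:
    """Per-sample speed (cm/s) of one tracked body point.

    Speed at sample ``i`` is the distance from sample ``i-1`` times the
    sample rate; the first sample is 0.  Spans adjacent to missing samples
    yield missing speed.  ``averaging_interval`` applies a centered boxcar
    (1 = raw).  ``despike`` applies a 3-sample median pre-filter to the raw
    speeds, a stand-in for the undocumented outlier filter of commercial
    trackers (off by default).
    """
    if averaging_interval < 1:
        raise ValueError("averaging_interval must be >= 1")
    xy = series.point(point)
    n = len(series)
    v = np.zeros(n)
    if n > 1:
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        v[1:] = d * series.sample_rate_hz
    if despike and n >= 3:
        finite = np.isfinite(v)
        tmp = v.copy()
        tmp[~finite] = 0.0
        tmp = medfilt(tmp, kernel_size=3)
        tmp[~finite] = np.nan
        v = tmp
    if averaging_interval > 1:
        v = _nan_boxcar(v, averaging_interval)
    return Signal(v, "cm/s", name=f"velocity[{point}]")


def compute_acceleration(velocity: Signal, sample_rate_hz: float) -> Signal:
    """Magnitude of the velocity first difference, in cm/s^2 (first sample 0)."""
    v = velocity.values
    a = np.zeros(len(v))
    if len(v) > 1:
        a[1:] = np.abs(np.diff(v)) * sample_rate_hz
    return Signal(a, "cm/s^2", name="acceleration")


def interpolate_gaps(series: TrackingSeries, max_gap_s: float) -> TrackingSeries:
    """Linearly bridge missing spans no longer than ``max_gap_s``.

    All coordinate and posture fields are interpolated across interior NaN
    runs of duration <= ``max_gap_s``; longer runs, and runs touching either
    end of the recording, stay missing.  Returns a new series with an updated
    missing mask.
    """
    out = series.copy()
    max_len = int(round(max_gap_s * series.sample_rate_hz))
    fields = [
        out.center_xy[:, 0], out.center_xy[:, 1],
        out.nose_xy[:, 0], out.nose_xy[:, 1],
        out.tail_xy[:, 0], out.tail_xy[:, 1],
        out.elongation_pct, out.body_angle_deg,
    ]
    for arr in fields:
        _fill_runs(arr, max_len)
    out.missing = out._nan_mask()
    return out


def _fill_runs(arr: np.ndarray, max_len: int) -> None:
    n = len(arr)
    isnan = np.isnan(arr)
    if not isnan.any() or max_len <= 0:
        return
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        # run is [i, j); needs finite anchors on both sides
        if i > 0 and j < n and (j - i) <= max_len:
            arr[i:j] = np.interp(np.arange(i, j), [i - 1, j], [arr[i - 1], arr[j]])
        i = j
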