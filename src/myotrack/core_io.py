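"""Tracking-session data model and the plain-text tracking-table dialect.

A session is a fixed-rate multi-point trajectory recorded by an overhead
home-cage tracker: per-sample coordinates (cm) of the animal's center-point,
nose-point and tail-base, plus two posture descriptors (body elongation in
percent, body bend angle in degrees).  Sessions round-trip losslessly through
a simple CSV dialect::

    # session_id: m01
    # sample_rate_hz: 25
    # arena_cm: 30 30
    time_s,center_x_cm,center_y_cm,nose_x_cm,nose_y_cm,tail_x_cm,tail_y_cm,elongation_pct,body_angle_deg
    0.0,15.0,15.0,...

'#'-prefixed comment lines are allowed before the header; empty cells mark
missing (lost-tracking) values; UTF-8, '.' decimal separator.  Missing samples
are kept explicit (NaN + mask) — interpolation is a deliberate kinematics
step, never done at read time.

Coordinate convention: origin at the arena's top-left corner as seen by the
camera, x to the right, y downward, units cm.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Column order of the tracking-table dialect.
COLUMNS = (
    "time_s",
    "center_x_cm",
    "center_y_cm",
    "nose_x_cm",
    "nose_y_cm",
    "tail_x_cm",
    "tail_y_cm",
    "elongation_pct",
    "body_angle_deg",
)

#: Default acquisition rate (samples/s).  Sample-count windows in the
#: detection profile (e.g. the 100-sample velocity average) are defined
#: relative to this rate; 25 Hz makes 100 samples = 4 s.
DEFAULT_SAMPLE_RATE_HZ = 25.0

#: Time-spacing tolerance (s) when checking the fixed-rate invariant.
SPACING_TOL_S = 1e-6


class TrackingFormatError(ValueError):
    """Malformed tracking table (bad header or cell)."""


class TrackingValidationError(ValueError):
    """Tracking table violates a series invariant (e.g. non-monotone time)."""


@dataclass
class Signal:
    """A per-sample scalar trace aligned to a :class:`TrackingSeries`.

    ``values`` uses NaN for missing samples.  ``unit`` is a plain string
    such as ``"cm/s"``, ``"cm/s^2"``, ``"%"`` or ``"deg"``.
    """

    values: np.ndarray
    unit: str
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.unit:
            raise ValueError("Signal unit must be non-empty")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TrackingSeries:
    """One recording session of a single animal.

    All per-sample arrays have equal length; coordinates are cm in the arena
    frame; ``missing`` flags samples where tracking was lost (any coordinate
    or posture cell empty).
    """

    session_id: str
    sample_rate_hz: float
    t: np.ndarray
    center_xy: np.ndarray
    nose_xy: np.ndarray
    tail_xy: np.ndarray
    elongation_pct: np.ndarray
    body_angle_deg: np.ndarray
    missing: np.ndarray | None = None
    arena_w_cm: float = 30.0
    arena_h_cm: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.center_xy = np.asarray(self.center_xy, dtype=float).reshape(-1, 2)
        self.nose_xy = np.asarray(self.nose_xy, dtype=float).reshape(-1, 2)
        self.tail_xy = np.asarray(self.tail_xy, dtype=float).reshape(-1, 2)
        self.elongation_pct = np.asarray(self.elongation_pct, dtype=float)
        self.body_angle_deg = np.asarray(self.body_angle_deg, dtype=float)
        n = len(self.t)
        lengths = {
            len(self.center_xy), len(self.nose_xy), len(self.tail_xy),
            len(self.elongation_pct), len(self.body_angle_deg),
        }
        if lengths - {n}:
            raise TrackingValidationError(
                f"per-sample arrays have unequal lengths {sorted(lengths | {n})}"
            )
        if self.missing is None:
            self.missing = self._nan_mask()
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if len(self.missing) != n:
                raise TrackingValidationError("missing mask length mismatch")
        if not (self.sample_rate_hz > 0):
            raise TrackingValidationError("sample_rate_hz must be positive")

    def _nan_mask(self) -> np.ndarray:
        cols = np.column_stack([
            self.center_xy, self.nose_xy, self.tail_xy,
            self.elongation_pct, self.body_angle_deg,
        ])
        return np.isnan(cols).any(axis=1)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self) * self.dt

    def copy(self) -> "TrackingSeries":
        return replace(
            self,
            t=self.t.copy(),
            center_xy=self.center_xy.copy(),
            nose_xy=self.nose_xy.copy(),
            tail_xy=self.tail_xy.copy(),
            elongation_pct=self.elongation_pct.copy(),
            body_angle_deg=self.body_angle_deg.copy(),
            missing=self.missing.copy(),
        )

    def point(self, label: str) -> np.ndarray:
        """Coordinate array for one of ``center``, ``nose``, ``tail_base``."""
        try:
            return {
                "center": self.center_xy,
                "nose": self.nose_xy,
                "tail_base": self.tail_xy,
            }[label]
        except KeyError:
            raise ValueError(
                f"unknown body point {label!r}; expected center/nose/tail_base"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "center_x_cm": self.center_xy[:, 0],
                "center_y_cm": self.center_xy[:, 1],
                "nose_x_cm": self.nose_xy[:, 0],
                "nose_y_cm": self.nose_xy[:, 1],
                "tail_x_cm": self.tail_xy[:, 0],
                "tail_y_cm": self.tail_xy[:, 1],
                "elongation_pct": self.elongation_pct,
                "body_angle_deg": self.body_angle_deg,
            }
        )


@dataclass
class Violation:
    """One invariant violation found by :func:`validate_series`."""

    index: int  # sample index, or -1 for series-level problems
    kind: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind} @ {self.index}] {self.message}"


def validate_series(series: TrackingSeries) -> list[Violation]:
    """Report every invariant violation of ``series`` (empty list iff valid).

    Checks: strictly increasing time with 1/rate spacing, coordinates inside
    the arena where not missing, elongation in [0, 100], body angle in
    [0, 180].  Reports, never raises.
    """
    out: list[Violation] = []
    t = series.t
    n = len(series)
    if n >= 2:
        d = np.diff(t)
        bad = np.where(d <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            out.append(Violation(i, "non-monotone-time",
                                 f"t[{i}]={t[i]!r} does not increase past t[{i-1}]={t[i-1]!r}"))
        else:
            off = np.where(np.abs(d - series.dt) > SPACING_TOL_S)[0]
            if off.size:
                i = int(off[0]) + 1
                out.append(Violation(i, "irregular-spacing",
                                     f"spacing {d[i-1]:.6g}s != 1/rate {series.dt:.6g}s"))
    ok = ~series.missing
    for label, xy in (("center", series.center_xy), ("nose", series.nose_xy),
                      ("tail_base", series.tail_xy)):
        with np.errstate(invalid="ignore"):
            bad = ok & (
                (xy[:, 0] < 0) | (xy[:, 0] > series.arena_w_cm)
                | (xy[:, 1] < 0) | (xy[:, 1] > series.arena_h_cm)
                | np.isnan(xy).any(axis=1)
            )
        for i in np.where(bad)[0]:
            out.append(Violation(int(i), "out-of-arena",
                                 f"{label} at ({xy[i, 0]:.3g}, {xy[i, 1]:.3g}) cm "
                                 f"outside [0,{series.arena_w_cm}]x[0,{series.arena_h_cm}]"))
    with np.errstate(invalid="ignore"):
        bad = ok & ((series.elongation_pct < 0) | (series.elongation_pct > 100))
    for i in np.where(bad)[0]:
        out.append(Violation(int(i), "elongation-range",
                             f"elongation {series.elongation_pct[i]:.3g}% outside [0,100]"))
    with np.errstate(invalid="ignore"):
        bad = ok & ((series.body_angle_deg < 0) | (series.body_angle_deg > 180))
    for i in np.where(bad)[0]:
        out.append(Violation(int(i), "body-angle-range",
                             f"body angle {series.body_angle_deg[i]:.3g} deg outside [0,180]"))
    return out


def _read_header_and_comments(path) -> tuple[dict, int]:
    """Scan leading '#' comments; return (metadata, header line number)."""
    meta: dict = {}
    lineno = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                lineno += 1
                continue
            if not stripped:
                lineno += 1
                continue
            cols = [c.strip() for c in stripped.split(",")]
            if tuple(cols) != COLUMNS:
                expected = set(COLUMNS)
                got = set(cols)
                extra = sorted(got - expected)
                miss = sorted(expected - got)
                detail = []
                if miss:
                    detail.append(f"missing column(s) {miss}")
                if extra:
                    detail.append(f"unexpected column(s) {extra}")
                if not detail:
                    detail.append(f"column order {cols} != {list(COLUMNS)}")
                raise TrackingFormatError(
                    f"{path}: malformed header: " + "; ".join(detail))
            return meta, lineno
    raise TrackingFormatError(f"{path}: no header line found")


def read_tracking_table(path, sample_rate_hz: float | None = None) -> TrackingSeries:
    """Read one session from the tracking CSV dialect.

    Empty cells become missing samples; the row count is always preserved.
    ``sample_rate_hz`` overrides both the file metadata and the rate inferred
    from the median time spacing.  Raises :class:`TrackingFormatError` for a
    malformed header and :class:`TrackingValidationError` for non-monotone
    time (first offending index named).
    """
    meta, header_line = _read_header_and_comments(path)
    df = pd.read_csv(path, skiprows=header_line, comment="#")
    t = df["time_s"].to_numpy(dtype=float)
    if np.isnan(t).any():
        i = int(np.where(np.isnan(t))[0][0])
        raise TrackingValidationError(f"{path}: empty time_s cell at row {i}")
    if len(t) >= 2:
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise TrackingValidationError(
                f"{path}: non-monotone time at sample {i} "
                f"(t[{i}]={t[i]!r} after t[{i-1}]={t[i-1]!r})")
    if sample_rate_hz is None:
        if "sample_rate_hz" in meta:
            sample_rate_hz = float(meta["sample_rate_hz"])
        elif len(t) >= 2:
            sample_rate_hz = 1.0 / float(np.median(np.diff(t)))
        else:
            sample_rate_hz = DEFAULT_SAMPLE_RATE_HZ
    arena_w, arena_h = 30.0, 30.0
    if "arena_cm" in meta:
        parts = meta["arena_cm"].split()
        arena_w, arena_h = float(parts[0]), float(parts[1])
    return TrackingSeries(
        session_id=meta.get("session_id", ""),
        sample_rate_hz=float(sample_rate_hz),
        t=t,
        center_xy=df[["center_x_cm", "center_y_cm"]].to_numpy(dtype=float),
        nose_xy=df[["nose_x_cm", "nose_y_cm"]].to_numpy(dtype=float),
        tail_xy=df[["tail_x_cm", "tail_y_cm"]].to_numpy(dtype=float),
        elongation_pct=df["elongation_pct"].to_numpy(dtype=float),
        body_angle_deg=df["body_angle_deg"].to_numpy(dtype=float),
        arena_w_cm=arena_w,
        arena_h_cm=arena_h,
    )


def write_tracking_table(series: TrackingSeries, path) -> str:
    """Write ``series`` in the dialect read by :func:`read_tracking_table`.

    Floats are written at full round-trip precision, so write -> read is the
    identity on all numeric fields.  Missing samples appear as empty cells.
    """
    buf = io.StringIO()
    buf.write(f"# session_id: {series.session_id}\n")
    buf.write(f"# sample_rate_hz: {series.sample_rate_hz!r}\n")
    buf.write(f"# arena_cm: {series.arena_w_cm!r} {series.arena_h_cm!r}\n")
    series.to_frame().to_csv(buf, index=False)  # default str() floats: lossless
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
    return str(path)


def apply_start_latency(series: TrackingSeries, latency_s: float = 3.0) -> TrackingSeries:
    """Trim the lead-in before the animal was continuously tracked.

    The recording proper starts once the center-point has been present in the
    arena for more than ``latency_s`` seconds; everything before that moment
    is dropped and time is re-zeroed.  Raises if no such run exists.
    """
    need = int(math.ceil(latency_s * series.sample_rate_hz))
    present = ~np.isnan(series.center_xy).any(axis=1)
    run = 0
    start = None
    for i, p in enumerate(present):
        run = run + 1 if p else 0
        if run >= max(need, 1):
            start = i + 1 if need else i
            break
    if start is None:
        raise TrackingValidationError(
            f"center-point never present for {latency_s} s continuously")
    out = replace(
        series,
        t=series.t[start:] - series.t[start],
        center_xy=series.center_xy[start:],
        nose_xy=series.nose_xy[start:],
        tail_xy=series.tail_xy[start:],
        elongation_pct=series.elongation_pct[start:],
        body_angle_deg=series.body_angle_deg[start:],
        missing=series.missing[start:],
    )
    return out
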