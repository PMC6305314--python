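"""Color-marker animal tracking and behavior-epoch annotation.

Markers (stickers, LEDs, dye spots) are detected per frame by HSV
thresholding; each marker's centroid is the intensity-weighted center of
the largest qualifying blob.  With two markers the animal's position is
their midpoint and its heading the angle of the marker-1 -> marker-2
vector; with one marker only position is available.  Behavior epochs are
labeled time intervals (up to 8 classes) on the behavior timebase,
mappable onto imaging frames with a constant offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv

from .io import BehaviorVideo, CalimbaError, Config

MAX_BEHAVIOR_LABELS = 8


class TooManyLabelsError(CalimbaError, ValueError):
    """More than the supported number of behavior labels."""


class EpochOrderError(CalimbaError, ValueError):
    """A stop event precedes its start, or an interval has end <= start."""


@dataclass
class HsvRange:
    """Closed HSV intervals: hue in degrees [0, 360) (may wrap through 0),
    saturation and value in [0, 1]."""

    hue: tuple[float, float]
    saturation: tuple[float, float] = (0.0, 1.0)
    value: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.saturation, self.value):
            if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0 and lo <= hi):
                raise ValueError("saturation/value intervals must be within [0, 1]")
        h0, h1 = self.hue
        if not (0.0 <= h0 < 360.0 and 0.0 <= h1 < 360.0):
            raise ValueError("hue bounds must be in [0, 360)")

    def mask(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels inside the range; hsv is skimage-style
        (h, s, v) in [0, 1]."""
        h = hsv[..., 0] * 360.0
        s = hsv[..., 1]
        v = hsv[..., 2]
        h0, h1 = self.hue
        if h0 <= h1:
            hue_ok = (h >= h0) & (h <= h1)
        else:  # wrapping interval, e.g. (340, 20)
            hue_ok = (h >= h0) | (h <= h1)
        return (
            hue_ok
            & (s >= self.saturation[0])
            & (s <= self.saturation[1])
            & (v >= self.value[0])
            & (v <= self.value[1])
        )


def preset_hsv(name: str, presets: dict | None = None) -> HsvRange:
    """Named marker preset (red/green/blue/yellow by default)."""
    table = presets if presets is not None else Config().hsv_presets
    if name not in table:
        raise KeyError(f"unknown HSV preset {name!r}; have {sorted(table)}")
    hue, sat, val = table[name]
    return HsvRange(hue=tuple(hue), saturation=tuple(sat), value=tuple(val))


@dataclass
class Track:
    """Per-frame marker centroids, validity, derived position and heading.

    ``markers`` is (T, n_markers, 2) in (row, col) pixels; invalid
    entries are NaN with ``valid`` False.  ``heading_deg`` (two-marker
    mode only) is the marker-1 -> marker-2 angle in [0, 360), 0 deg
    toward +col, counter-clockwise positive under the y-up convention.
    """

    markers: np.ndarray
    valid: np.ndarray
    frame_rate_hz: float
    px_per_cm: float | None = None
    interpolated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.markers.ndim != 3 or self.markers.shape[2] != 2:
            raise ValueError("markers must be (T, n_markers, 2)")
        if self.valid.shape != self.markers.shape[:2]:
            raise ValueError("valid flags shape mismatch")
        if self.interpolated is None:
            self.interpolated = np.zeros_like(self.valid)

    @property
    def n_frames(self) -> int:
        return self.markers.shape[0]

    @property
    def n_markers(self) -> int:
        return self.markers.shape[1]

    @property
    def frame_valid(self) -> np.ndarray:
        """Frame counts as tracked when every marker is valid."""
        return self.valid.all(axis=1)

    @property
    def position(self) -> np.ndarray:
        """(T, 2) animal position: marker midpoint (or the single marker);
        NaN where the frame is untracked."""
        pos = self.markers.mean(axis=1)
        pos[~self.frame_valid] = np.nan
        return pos

    @property
    def heading_deg(self) -> np.ndarray:
        """(T,) heading; NaN in single-marker mode or untracked frames."""
        out = np.full(self.n_frames, np.nan)
        if self.n_markers < 2:
            return out
        ok = self.frame_valid
        p1 = self.markers[ok, 0]
        p2 = self.markers[ok, 1]
        out[ok] = [heading(tuple(a), tuple(b)) for a, b in zip(p1, p2)]
        return out

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def to_frame(self) -> pd.DataFrame:
        """Long table: frame, t_s, per-marker row/col/valid, heading."""
        cols: dict[str, np.ndarray] = {
            "frame": np.arange(self.n_frames),
            "t_s": self.times_s,
        }
        for m in range(self.n_markers):
            cols[f"m{m + 1}_row"] = self.markers[:, m, 0]
            cols[f"m{m + 1}_col"] = self.markers[:, m, 1]
            cols[f"valid{m + 1}"] = self.valid[:, m].astype(int)
        pos = self.position
        cols["pos_row"] = pos[:, 0]
        cols["pos_col"] = pos[:, 1]
        cols["heading_deg"] = self.heading_deg
        return pd.DataFrame(cols)


@dataclass
class BehaviorEpochs:
    """Labeled behavior intervals (label, start_s, end_s), at most 8 labels."""

    intervals: list[tuple[str, float, float]]
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        labels = self.labels
        if len(labels) > MAX_BEHAVIOR_LABELS:
            raise TooManyLabelsError(
                f"{len(labels)} labels exceed the supported maximum of {MAX_BEHAVIOR_LABELS}"
            )
        for lbl, s, e in self.intervals:
            if s < 0 or e <= s:
                raise EpochOrderError(f"bad interval {lbl!r}: ({s}, {e})")
        if not self.allow_overlap:
            marks = sorted(self.intervals, key=lambda iv: iv[1])
            for (l1, s1, e1), (l2, s2, e2) in zip(marks, marks[1:]):
                if s2 < e1 and l1 != l2:
                    raise EpochOrderError(
                        f"overlapping intervals of different labels: {l1!r} and {l2!r}"
                    )

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for lbl, _, _ in self.intervals:
            if lbl not in seen:
                seen.append(lbl)
        return seen

    def label_at(self, t_s: float) -> str | None:
        """Label containing time t under the half-open [start, end) rule."""
        for lbl, s, e in self.intervals:
            if s <= t_s < e:
                return lbl
        return None

    def duration(self, label: str) -> float:
        return sum(e - s for lbl, s, e in self.intervals if lbl == label)


def heading(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Angle of the p1 -> p2 vector in degrees [0, 360).

    Points are (row, col); 0 deg points toward increasing column and
    angles grow counter-clockwise with image rows flipped to y-up
    (so p2 one row above p1 gives 90 deg).  Coincident points are
    undefined and raise ValueError.
    """
    dr = float(p2[0]) - float(p1[0])
    dc = float(p2[1]) - float(p1[1])
    if dr == 0.0 and dc == 0.0:
        raise ValueError("heading undefined for coincident points")
    return float(np.degrees(np.arctan2(-dr, dc)) % 360.0)


def track_markers(
    video: BehaviorVideo,
    hsv_ranges: Sequence[HsvRange],
    min_blob_px: int = 10,
    px_per_cm: float | None = None,
) -> Track:
    """Detect 1 or 2 color markers in every frame.

    Per frame and per range: HSV-threshold, keep the largest connected
    blob of at least ``min_blob_px`` pixels (robustness against
    reflections and small distractors), centroid = value-channel-weighted
    center of the blob.  Frames without a qualifying blob get the invalid
    flag; no exception is raised per frame.
    """
    if not 1 <= len(hsv_ranges) <= 2:
        raise ValueError("provide 1 or 2 HSV ranges")
    frames = np.asarray(video.frames)
    if frames.dtype.kind in "ui":
        rgb = frames.astype(float) / 255.0
    else:
        rgb = frames.astype(float)
    T = frames.shape[0]
    n_markers = len(hsv_ranges)
    markers = np.full((T, n_markers, 2), np.nan)
    valid = np.zeros((T, n_markers), dtype=bool)
    for t in range(T):
        hsv = rgb2hsv(rgb[t])
        for m, rng in enumerate(hsv_ranges):
            mask = rng.mask(hsv)
            if not mask.any():
                continue
            labeled, n = ndimage.label(mask)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
            best = int(np.argmax(sizes)) + 1
            if sizes[best - 1] < min_blob_px:
                continue
            blob = labeled == best
            weights = hsv[..., 2] * blob
            total = weights.sum()
            rr, cc = np.nonzero(blob)
            w = weights[rr, cc] / total
            markers[t, m] = (float(np.dot(rr, w)), float(np.dot(cc, w)))
            valid[t, m] = True
    return Track(
        markers=markers,
        valid=valid,
        frame_rate_hz=video.frame_rate_hz,
        px_per_cm=px_per_cm,
    )


def quality_report(track: Track) -> dict:
    """Untracked-frame summary: fraction, run lengths, longest gap,
    per-marker valid counts."""
    fv = track.frame_valid
    invalid = ~fv
    runs: list[int] = []
    count = 0
    for bad in invalid:
        if bad:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return {
        "n_frames": track.n_frames,
        "n_untracked": int(invalid.sum()),
        "untracked_fraction": float(invalid.mean()),
        "untracked_percent": float(100.0 * invalid.mean()),
        "gap_run_lengths": runs,
        "longest_gap": max(runs, default=0),
        "per_marker_valid": [int(v) for v in track.valid.sum(axis=0)],
    }


def interpolate_gaps(track: Track, max_gap_s: float = 0.5) -> Track:
    """Linearly interpolate marker positions across short invalid runs.

    Runs longer than ``max_gap_s`` (or touching the series ends) are left
    invalid; interpolated frames are flagged in ``interpolated``.
    """
    max_gap = int(round(max_gap_s * track.frame_rate_hz))
    markers = track.markers.copy()
    valid = track.valid.copy()
    interp = track.interpolated.copy()
    T = track.n_frames
    for m in range(track.n_markers):
        col_valid = valid[:, m]
        t = 0
        while t < T:
            if col_valid[t]:
                t += 1
                continue
            start = t
            while t < T and not col_valid[t]:
                t += 1
            end = t  # run is [start, end)
            length = end - start
            if start == 0 or end == T or length > max_gap:
                continue
            a, b = markers[start - 1, m], markers[end, m]
            for k in range(length):
                frac = (k + 1) / (length + 1)
                markers[start + k, m] = a + frac * (b - a)
                valid[start + k, m] = True
                interp[start + k, m] = True
    return Track(
        markers=markers,
        valid=valid,
        frame_rate_hz=track.frame_rate_hz,
        px_per_cm=track.px_per_cm,
        interpolated=interp,
    )


def map_track_to_imaging(
    track: Track,
    imaging_frame_rate_hz: float,
    n_imaging_frames: int,
    offset_s: float = 0.0,
) -> dict:
    """Nearest-neighbor resampling of the track onto imaging frame times.

    Imaging frame k (time ``k / imaging_rate``) reads the behavior frame
    nearest to ``k / imaging_rate + offset_s``.  Raises when the offset
    pushes every imaging frame outside the tracked interval.
    """
    if imaging_frame_rate_hz <= 0:
        raise ValueError("imaging frame rate must be positive")
    t_img = np.arange(n_imaging_frames) / imaging_frame_rate_hz + offset_s
    idx = np.round(t_img * track.frame_rate_hz).astype(int)
    in_range = (idx >= 0) & (idx < track.n_frames)
    if not in_range.any():
        raise ValueError("offset places all imaging frames outside the track")
    idx_c = np.clip(idx, 0, track.n_frames - 1)
    pos = track.position[idx_c]
    heading_series = track.heading_deg[idx_c]
    fvalid = track.frame_valid[idx_c] & in_range
    pos[~fvalid] = np.nan
    heading_series[~fvalid] = np.nan
    return {
        "position": pos,
        "heading_deg": heading_series,
        "valid": fvalid,
        "behavior_index": idx_c,
        "in_range": in_range,
    }


def map_epochs_to_imaging(
    epochs: BehaviorEpochs,
    imaging_frame_rate_hz: float,
    n_imaging_frames: int,
    offset_s: float = 0.0,
    unlabeled: str = "unlabeled",
) -> np.ndarray:
    """Per-imaging-frame behavior label (the half-open [start, end) rule)."""
    t_img = np.arange(n_imaging_frames) / imaging_frame_rate_hz + offset_s
    return np.array([epochs.label_at(t) or unlabeled for t in t_img], dtype=object)


def map_timebase(
    track_or_epochs: Track | BehaviorEpochs,
    imaging_frame_rate_hz: float,
    n_imaging_frames: int,
    offset_s: float = 0.0,
):
    """Dispatch to the track or epoch resampler (shared entry point)."""
    if isinstance(track_or_epochs, Track):
        return map_track_to_imaging(
            track_or_epochs, imaging_frame_rate_hz, n_imaging_frames, offset_s
        )
    return map_epochs_to_imaging(
        track_or_epochs, imaging_frame_rate_hz, n_imaging_frames, offset_s
    )


def annotate(
    events: Sequence[tuple[str, float, Literal["start", "stop"]]],
    video_duration_s: float | None = None,
    allow_overlap: bool = False,
) -> BehaviorEpochs:
    """Build epochs from a chronological keypress-style event list.

    Each event is ``(label, timestamp_s, 'start'|'stop')``.  An unclosed
    start is closed at ``video_duration_s`` with a warning; a stop
    without a matching start, or more than 8 distinct labels, is an
    error.
    """
    open_starts: dict[str, float] = {}
    intervals: list[tuple[str, float, float]] = []
    labels: set[str] = set()
    for lbl, ts, kind in events:
        labels.add(lbl)
        if len(labels) > MAX_BEHAVIOR_LABELS:
            raise TooManyLabelsError(
                f"label {lbl!r} is the {len(labels)}th distinct label; max is {MAX_BEHAVIOR_LABELS}"
            )
        if kind == "start":
            if lbl in open_starts:
                raise EpochOrderError(f"{lbl!r} started twice without a stop")
            open_starts[lbl] = float(ts)
        elif kind == "stop":
            if lbl not in open_starts:
                raise EpochOrderError(f"stop of {lbl!r} at {ts} without a start")
            start = open_starts.pop(lbl)
            if ts <= start:
                raise EpochOrderError(f"{lbl!r} stops at {ts} before its start {start}")
            intervals.append((lbl, start, float(ts)))
        else:
            raise ValueError(f"event kind must be 'start' or 'stop', got {kind!r}")
    for lbl, start in sorted(open_starts.items()):
        if video_duration_s is None or video_duration_s <= start:
            raise EpochOrderError(f"unclosed start of {lbl!r} and no usable video end")
        warnings.warn(
            f"behavior {lbl!r} started at {start} s but never stopped; "
            f"closing at video end ({video_duration_s} s)",
            stacklevel=2,
        )
        intervals.append((lbl, start, float(video_duration_s)))
    intervals.sort(key=lambda iv: iv[1])
    return BehaviorEpochs(intervals=intervals, allow_overlap=allow_overlap)


def epochs_from_frame(df: pd.DataFrame, allow_overlap: bool = False) -> BehaviorEpochs:
    """Epochs from a table with columns label, start_s, end_s."""
    intervals = [
        (str(r.label), float(r.start_s), float(r.end_s)) for r in df.itertuples()
    ]
    return BehaviorEpochs(intervals=intervals, allow_overlap=allow_overlap)
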