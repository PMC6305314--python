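"""Joint calcium-behavior analyses: spatial event maps with orientation,
per-behavior event rates and rasters, trigger-aligned sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorEpochs
from .io import CalimbaError


class NoValidPositionError(CalimbaError, ValueError):
    """No valid animal position available for spatial mapping."""


class NoCompleteWindowError(CalimbaError, ValueError):
    """Every trigger's analysis window extends outside the recording."""


@dataclass
class SpatialEventMap:
    """Event counts, occupancy (s) and event rate (Hz) on a spatial grid.

    ``rate_map`` is NaN-masked where occupancy is below ``min_occ_s``;
    ``event_points`` lists (row, col, heading_deg) at each mapped event so
    orientation arrows can be drawn; ``n_excluded`` counts events that
    fell on untracked frames.
    """

    bins: np.ndarray
    occupancy: np.ndarray
    rate_map: np.ndarray
    event_points: list[tuple[float, float, float]]
    bin_px: float
    min_occ_s: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.bins.shape != self.occupancy.shape:
            raise ValueError("bins/occupancy shape mismatch")


@dataclass
class SweepStack:
    """Trigger-aligned trace segments: trials x window, with mean +/- SEM."""

    window_s: tuple[float, float]
    times_s: np.ndarray
    trials: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_dropped: int = 0
    trigger_times_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def spatial_event_map(
    event_frames: Sequence[int],
    position: np.ndarray,
    valid: np.ndarray,
    heading_deg: np.ndarray | None,
    frame_rate_hz: float,
    frame_shape: tuple[int, int],
    bin_px: float = 20.0,
    min_occ_s: float = 0.2,
    warn_threshold: float = 0.9,
) -> SpatialEventMap:
    """Bin calcium events by the animal's position.

    ``position``/``valid``/``heading_deg`` are per-imaging-frame series
    (see :func:`calimba.behavior.map_track_to_imaging`); occupancy counts
    every valid frame at one frame period each; the rate map divides
    event counts by occupancy, masked (NaN) below ``min_occ_s``.  Events
    on untracked frames are excluded and tallied in ``n_excluded``; a
    UserWarning fires when fewer than ``warn_threshold`` of the events
    have a valid position.
    """
    position = np.asarray(position, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if not valid.any():
        raise NoValidPositionError("track has no valid positions")
    H, W = frame_shape
    n_rows = int(np.ceil(H / bin_px))
    n_cols = int(np.ceil(W / bin_px))
    occupancy = np.zeros((n_rows, n_cols))
    frame_period = 1.0 / frame_rate_hz

    def bin_of(p):
        r = min(n_rows - 1, max(0, int(p[0] // bin_px)))
        c = min(n_cols - 1, max(0, int(p[1] // bin_px)))
        return r, c

    for t in np.nonzero(valid)[0]:
        r, c = bin_of(position[t])
        occupancy[r, c] += frame_period

    bins = np.zeros((n_rows, n_cols))
    event_points: list[tuple[float, float, float]] = []
    n_excluded = 0
    for f in event_frames:
        f = int(f)
        if f < 0 or f >= len(valid) or not valid[f]:
            n_excluded += 1
            continue
        r, c = bin_of(position[f])
        bins[r, c] += 1
        hd = float(heading_deg[f]) if heading_deg is not None else np.nan
        event_points.append((float(position[f][0]), float(position[f][1]), hd))

    n_events = len(list(event_frames))
    if n_events and (n_events - n_excluded) / n_events < warn_threshold:
        import warnings

        warnings.warn(
            f"{n_excluded}/{n_events} events fell on untracked frames", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = bins / occupancy
    rate[occupancy < min_occ_s] = np.nan
    return SpatialEventMap(
        bins=bins,
        occupancy=occupancy,
        rate_map=rate,
        event_points=event_points,
        bin_px=bin_px,
        min_occ_s=min_occ_s,
        n_excluded=n_excluded,
    )


def event_rate_by_behavior(
    event_frames: Sequence[int],
    frame_labels: np.ndarray,
    frame_rate_hz: float,
    unlabeled: str = "unlabeled",
) -> pd.DataFrame:
    """Event rate (Hz) per behavior label.

    ``frame_labels`` assigns a label to every imaging frame (the
    unlabeled pseudo-label included); each label's duration is its frame
    count times the frame period.  ``rate = count / duration``.  Exact
    conservation holds: summing ``rate * duration`` over labels returns
    the total event count.
    """
    frame_labels = np.asarray(frame_labels, dtype=object)
    period = 1.0 / frame_rate_hz
    labels = list(dict.fromkeys(frame_labels.tolist()))
    rows = []
    for lbl in labels:
        sel = frame_labels == lbl
        duration = float(sel.sum()) * period
        if duration == 0:
            raise ValueError(f"label {lbl!r} has zero duration")
        count = int(sum(1 for f in event_frames if 0 <= int(f) < len(frame_labels) and frame_labels[int(f)] == lbl))
        rows.append({"label": lbl, "n_events": count, "duration_s": duration,
                     "rate_hz": count / duration})
    return pd.DataFrame(rows, columns=["label", "n_events", "duration_s", "rate_hz"])


def normalized_activity_by_behavior(
    events_per_roi: Sequence[Sequence[int]],
    frame_labels: np.ndarray,
    frame_rate_hz: float,
) -> pd.DataFrame:
    """Per-ROI z-scored event rate per behavior.

    For each ROI, its per-label rates are standardized across labels
    (zero mean, unit SD); this package's convention for a normalized
    activity plot.
    """
    records = []
    for i, ev in enumerate(events_per_roi):
        table = event_rate_by_behavior(ev, frame_labels, frame_rate_hz)
        rates = table["rate_hz"].to_numpy()
        sd = rates.std()
        z = (rates - rates.mean()) / sd if sd > 0 else np.zeros_like(rates)
        for lbl, rate, zz in zip(table["label"], rates, z):
            records.append({"roi": i, "label": lbl, "rate_hz": rate, "z_rate": zz})
    return pd.DataFrame(records, columns=["roi", "label", "rate_hz", "z_rate"])


def raster(
    events_per_roi: Sequence[Sequence[int]],
    frame_rate_hz: float,
    n_frames: int,
    frame_labels: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Plot-ready long table of events plus the population event rate.

    Returns ``(table, population_rate)`` where the table has one row per
    (roi, event) with its time and behavior label, and
    ``population_rate[t]`` is the summed event count across ROIs in frame
    t times the frame rate (Hz).  The population rate integrates back to
    the total event count.
    """
    rows = []
    population = np.zeros(n_frames)
    for i, ev in enumerate(events_per_roi):
        for f in ev:
            f = int(f)
            lbl = frame_labels[f] if frame_labels is not None and f < len(frame_labels) else ""
            rows.append({"roi": i, "frame": f, "t_s": f / frame_rate_hz, "label": lbl})
            if 0 <= f < n_frames:
                population[f] += 1
    table = pd.DataFrame(rows, columns=["roi", "frame", "t_s", "label"])
    return table, population * frame_rate_hz


def sweep_align(
    trace: np.ndarray,
    triggers_s: Sequence[float],
    pre_s: float,
    post_s: float,
    frame_rate_hz: float,
) -> SweepStack:
    """Align a trace to triggers and stack the windows.

    Windows span ``[-pre_s, +post_s]`` around each trigger; triggers
    whose window is truncated by the recording edges are dropped and
    counted.  Rows are ordered by trigger time; ``mean`` and ``sem``
    (sample SD / sqrt(n)) are computed per time point.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    trace = np.asarray(trace, dtype=float)
    T = trace.size
    pre = int(round(pre_s * frame_rate_hz))
    post = int(round(post_s * frame_rate_hz))
    times = np.arange(-pre, post + 1) / frame_rate_hz
    rows = []
    kept_triggers = []
    dropped = 0
    for ts in sorted(float(t) for t in triggers_s):
        center = int(round(ts * frame_rate_hz))
        if center - pre < 0 or center + post >= T:
            dropped += 1
            continue
        rows.append(trace[center - pre : center + post + 1])
        kept_triggers.append(ts)
    if not rows:
        raise NoCompleteWindowError("no trigger has a complete window in the recording")
    trials = np.stack(rows)
    mean = trials.mean(axis=0)
    n = trials.shape[0]
    sem = trials.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return SweepStack(
        window_s=(pre_s, post_s),
        times_s=times,
        trials=trials,
        mean=mean,
        sem=sem,
        n_dropped=dropped,
        trigger_times_s=np.asarray(kept_triggers),
    )
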