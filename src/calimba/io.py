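"""Movie / behavior-video I/O, result export, and configuration.

All timebase metadata (frame rates, pixel size) lives on the container
objects defined here.  Pixel coordinates are 0-based ``(row, col)`` with
the origin at the top-left; time indices are 0-based.  Internal compute
dtype is floating point regardless of storage dtype; movie writes default
to 32-bit float TIFF.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile


class CalimbaError(Exception):
    """Base class for all errors raised by this package."""


class MissingFileError(CalimbaError, FileNotFoundError):
    """Input path does not exist or is not readable."""


class EmptyMovieError(CalimbaError, ValueError):
    """A movie or video source contained zero frames."""


class NonUniformFrameError(CalimbaError, ValueError):
    """TIFF pages (or video frames) differ in size."""


class DtypeRangeError(CalimbaError, ValueError):
    """Pixel values do not fit the requested storage dtype."""


class InconsistentLengthError(CalimbaError, ValueError):
    """Series that must share a timebase have different lengths."""


@dataclass
class Movie:
    """A fluorescence movie: ``data[t, row, col]`` plus timebase metadata.

    Parameters
    ----------
    data
        time x height x width array of non-negative fluorescence
        intensities (arbitrary units).  Stored as float64 internally.
    frame_rate_hz
        Acquisition rate in Hz; must be positive.
    pixel_size_um
        Physical size of one pixel in micrometers; must be positive.
    origin
        Free-form provenance string (file path, generator name, ...).
    """

    data: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    origin: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D (t, h, w), got {self.data.ndim}-D")
        if min(self.data.shape) < 1:
            raise EmptyMovieError("movie has an empty dimension")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie data contains non-finite values")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times_s(self) -> np.ndarray:
        """Frame timestamps in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.frame_rate_hz

    def with_data(self, data: np.ndarray, **overrides) -> "Movie":
        """Copy of this movie with new pixel data (metadata carried over)."""
        kwargs = dict(
            frame_rate_hz=self.frame_rate_hz,
            pixel_size_um=self.pixel_size_um,
            origin=self.origin,
        )
        kwargs.update(overrides)
        return Movie(data=data, **kwargs)


@dataclass
class BehaviorVideo:
    """A color behavior video: ``frames[t, row, col, channel]`` in RGB order."""

    frames: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("behavior video must be (t, h, w, 3) RGB")
        if self.frames.shape[0] < 1:
            raise EmptyMovieError("behavior video has zero frames")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# Parameter ranges documented per field: (low, high), closed intervals.
_CONFIG_RANGES: dict[str, tuple[float, float]] = {
    "downsample_factor": (0.01, 1.0),
    "downsample_trigger_width_px": (1, 100_000),
    "corrupt_thr_multiplier": (0.0, 100.0),
    "corrupt_mad_const": (1e-6, 10.0),
    "dust_ring_width_px": (1, 1000),
    "roi_min_area_px": (1, 1_000_000),
    "roi_max_area_px": (1, 1_000_000),
    "roundness_min": (0.0, 1.0),
    "overlap_merge_frac": (0.0, 1.0),
    "trace_corr_merge": (-1.0, 1.0),
    "neuropil_ring_width_um": (0.0, 1000.0),
    "neuropil_r": (0.0, 2.0),
    "low_fluor_quantile": (0.0, 1.0),
}


@dataclass
class Config:
    """Pipeline parameters with the published defaults.

    Every numeric parameter is validated against a documented closed
    range.  ``hsv_presets`` maps marker names to HSV interval triples on
    the (hue deg, saturation, value) scales used by
    :mod:`calimba.behavior`.
    """

    downsample_factor: float = 0.40
    downsample_trigger_width_px: int = 100
    corrupt_thr_multiplier: float = 5.0
    corrupt_mad_const: float = 0.6745
    dust_ring_width_px: int = 8
    roi_min_area_px: int = 30
    roi_max_area_px: int = 300
    roundness_min: float = 0.6
    overlap_merge_frac: float = 0.30
    trace_corr_merge: float = 0.8
    neuropil_ring_width_um: float = 20.0
    neuropil_r: float = 0.7
    low_fluor_quantile: float = 0.05
    hsv_presets: dict = field(default_factory=lambda: dict(DEFAULT_HSV_PRESETS))
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _CONFIG_RANGES.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ValueError(f"config.{name}={value!r} outside [{lo}, {hi}]")
        if self.roi_min_area_px > self.roi_max_area_px:
            raise ValueError("roi_min_area_px must not exceed roi_max_area_px")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_json(cls, path: str | Path) -> "Config":
        return cls.from_dict(json.loads(Path(path).read_text()))


# LED/sticker-like marker colors as (hue interval deg, sat interval, val interval).
DEFAULT_HSV_PRESETS: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "red": ((340.0, 20.0), (0.5, 1.0), (0.3, 1.0)),  # hue wraps through 0
    "green": ((90.0, 150.0), (0.5, 1.0), (0.3, 1.0)),
    "blue": ((200.0, 260.0), (0.5, 1.0), (0.3, 1.0)),
    "yellow": ((40.0, 70.0), (0.5, 1.0), (0.3, 1.0)),
}


def read_movie(path: str | Path, frame_rate_hz: float, pixel_size_um: float) -> Movie:
    """Read a multi-page TIFF stack as a :class:`Movie`.

    Page order is preserved as time order.  Frame rate and pixel size are
    caller inputs; vendor TIFF tags are deliberately ignored because they
    vary between recorders.
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(str(path))
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        if len(pages) == 0:
            raise EmptyMovieError(f"{path} has zero pages")
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise NonUniformFrameError(f"{path} pages differ in size: {sorted(shapes)}")
        data = tf.asarray()
    if data.ndim == 2:  # single page
        data = data[None]
    return Movie(
        data=data.astype(np.float64),
        frame_rate_hz=frame_rate_hz,
        pixel_size_um=pixel_size_um,
        origin=str(path),
    )


def write_movie(movie: Movie, path: str | Path, dtype: str = "float32") -> Path:
    """Write a movie as multi-page TIFF; default storage dtype is float32.

    Integer dtypes raise :class:`DtypeRangeError` when pixel values do
    not fit, rather than silently wrapping.
    """
    path = Path(path)
    dt = np.dtype(dtype)
    data = movie.data
    if dt.kind in "iu":
        info = np.iinfo(dt)
        if data.min() < info.min or data.max() > info.max:
            raise DtypeRangeError(
                f"data range [{data.min()}, {data.max()}] exceeds {dt} range"
            )
        out = np.round(data).astype(dt)
    else:
        out = data.astype(dt)
    tifffile.imwrite(path, out)
    return path


def read_behavior_video(path: str | Path, frame_rate_hz: float | None = None) -> BehaviorVideo:
    """Read a color behavior video.

    Multi-page TIFF (``.tif``/``.tiff``, shape t x h x w x 3 or t x h x w)
    is the always-available portable format; AVI/MP4 are decoded through
    imageio when an ffmpeg-capable plugin is installed.  Grayscale input
    is promoted to 3 identical channels (documented convention).
    """
    path = Path(path)
    if not path.is_file():
        raise MissingFileError(str(path))
    suffix = path.suffix.lower()
    fps = frame_rate_hz
    if suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if fps is None:
            fps = 30.0
    else:
        import imageio.v2 as iio

        try:
            reader = iio.get_reader(path)
        except Exception as exc:  # codec/plugin missing or file truncated
            raise CalimbaError(f"cannot decode {path}: {exc}") from exc
        try:
            meta = reader.get_meta_data()
            frames = np.stack([np.asarray(f) for f in reader])
        except Exception as exc:
            raise CalimbaError(f"cannot decode frames of {path}: {exc}") from exc
        finally:
            reader.close()
        if fps is None:
            fps = float(meta.get("fps", 30.0))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 3:  # grayscale stack -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=-1)
    if frames.shape[-1] == 4:  # drop alpha
        frames = frames[..., :3]
    if frames.shape[0] == 0:
        raise EmptyMovieError(f"{path} has zero frames")
    return BehaviorVideo(frames=frames, frame_rate_hz=float(fps))


def write_behavior_video(video: BehaviorVideo, path: str | Path) -> Path:
    """Write a behavior video as a color multi-page TIFF (portable format)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(video.frames, dtype=np.uint8))
    return path


def export_results(
    outdir: str | Path,
    bundle=None,
    rois=None,
    track=None,
    epochs=None,
    config: Config | None = None,
    seed: int | None = None,
    extra_metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Export traces, events, track, and epochs as CSV plus a JSON manifest.

    Returns a manifest mapping logical names to written paths.  Exports
    are deterministic: identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    if bundle is not None:
        t = bundle.n_frames
        cols: dict[str, np.ndarray] = {"frame": np.arange(t)}
        cols["t_s"] = np.arange(t) / bundle.frame_rate_hz
        for kind in ("raw", "neuropil", "corrected", "detrended", "denoised", "spikes"):
            series = getattr(bundle, kind)
            if series is None:
                continue
            if series.shape[-1] != t:
                raise InconsistentLengthError(
                    f"{kind} length {series.shape[-1]} != {t} frames"
                )
            for i in range(series.shape[0]):
                cols[f"roi{i:03d}_{kind}"] = series[i]
        traces_path = outdir / "traces.csv"
        df = pd.DataFrame(cols)
        if len(cols) == 2:  # no ROI columns: write the header only
            df = df.iloc[0:0]
        df.to_csv(traces_path, index=False, float_format="%.9g")
        manifest["traces"] = traces_path

        if bundle.events is not None:
            rows = [
                {"roi": i, "frame": int(e), "t_s": e / bundle.frame_rate_hz}
                for i, ev in enumerate(bundle.events)
                for e in ev
            ]
            events_path = outdir / "events.csv"
            pd.DataFrame(rows, columns=["roi", "frame", "t_s"]).to_csv(
                events_path, index=False, float_format="%.9g"
            )
            manifest["events"] = events_path

    if rois is not None:
        from . import cells  # local import to avoid cycle

        rois_tif = outdir / "rois.tif"
        rois_json = outdir / "rois.json"
        cells.save_roiset(rois, rois_tif, rois_json)
        manifest["rois"] = rois_tif
        manifest["rois_meta"] = rois_json

    if track is not None:
        track_path = outdir / "track.csv"
        track.to_frame().to_csv(track_path, index=False, float_format="%.9g")
        manifest["track"] = track_path

    if epochs is not None:
        ep_path = outdir / "epochs.csv"
        pd.DataFrame(
            [(lbl, s, e) for lbl, s, e in epochs.intervals],
            columns=["label", "start_s", "end_s"],
        ).to_csv(ep_path, index=False, float_format="%.9g")
        manifest["epochs"] = ep_path

    meta = {
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "package": "calimba",
    }
    if extra_metadata:
        meta.update(dict(extra_metadata))
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    manifest["metadata"] = meta_path
    return manifest
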