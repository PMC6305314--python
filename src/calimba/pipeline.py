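"""End-to-end orchestration of the imaging, behavior and joint workflows.

The imaging pipeline runs the five stages in order: pre-processing,
motion correction, dF/F calculation, cell detection, and calcium trace
analyses.  Each run produces a manifest (config snapshot, input hashes,
stage list with timestamps, seed); two runs from identical config + seed
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import activity, behavior, cells, preprocess, registration, traces
from .io import Config, Movie, export_results

logger = logging.getLogger("calimba")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in args[0]."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(stage, cause)
        self.stage = stage
        self.cause = cause

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"stage {self.stage!r} failed: {self.cause}"


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config: dict
    seed: int
    input_hashes: dict[str, str] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, **info: Any) -> None:
        self.stages.append({"stage": name, "wall_time": time.time(), **info})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


@dataclass
class ImagingResult:
    movie_pre: Movie
    movie_registered: Movie
    dff: activity.DffMovie
    projection: np.ndarray
    rois: cells.RoiSet
    bundle: traces.TraceBundle | None
    shifts: registration.ShiftSeries
    manifest: RunManifest


def run_imaging_pipeline(
    movie: Movie,
    config: Config | None = None,
    n_ics: int | None = None,
    register_method: str = "subpixel",
    dust_region: preprocess.DustRegion | None = None,
    expected_cells: int = 10,
    outdir: str | Path | None = None,
) -> ImagingResult:
    """Pre-process -> motion-correct -> dF/F -> detect cells -> traces."""
    cfg = config or Config()
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.random_seed)
    manifest.input_hashes["movie"] = _hash_array(movie.data)

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.add_stage(name)
        return out

    # --- pre-processing
    if dust_region is not None:
        movie = stage("dust_removal", preprocess.remove_dust, movie, dust_region)
    stats = stage("corrupt_threshold", preprocess.compute_corrupt_threshold,
                  movie, cfg.corrupt_thr_multiplier, cfg.corrupt_mad_const)
    flagged = preprocess.detect_corrupt_frames(movie, stats)
    movie = stage("replace_frames", preprocess.replace_frames, movie, flagged)
    movie = stage("downsample", preprocess.downsample, movie,
                  cfg.downsample_factor, cfg.downsample_trigger_width_px)
    movie_pre = stage("flatfield", preprocess.flatfield_correct, movie)

    # --- motion correction
    # the temporal mean is the default reference: it is dominated by
    # stable anatomy rather than whichever transient happens to be active
    reg_fn = (registration.register_lucas_kanade if register_method == "lk"
              else registration.register_subpixel)
    registered, shifts = stage("register", reg_fn, movie_pre,
                               static_reference="mean")
    registered = stage("crop_to_valid", registration.crop_to_valid, registered, shifts)

    # --- dF/F + projection
    dff = stage("dff", activity.delta_f_over_f, registered)
    projection = stage("projection", activity.max_projection_weighted, dff)

    # --- cell detection + refinement
    n_pcs = min(3 * expected_cells, dff.n_frames - 1,
                dff.frame_shape[0] * dff.frame_shape[1])
    n_ics = n_ics or n_pcs
    ica = stage("pca_ica", cells.pca_ica, dff, n_pcs, n_ics, 0.5, cfg.random_seed)
    rois = stage("filters_to_rois", cells.filters_to_rois, ica)
    rois = stage("refine", cells.refine, rois, registered,
                 None,
                 cfg.roi_min_area_px, cfg.roi_max_area_px, cfg.roundness_min,
                 cfg.overlap_merge_frac, cfg.low_fluor_quantile, cfg.trace_corr_merge)

    # --- trace analyses
    bundle = None
    if len(rois):
        bundle = stage("traces", traces.process_traces, dff, rois,
                       cfg.neuropil_r, cfg.neuropil_ring_width_um)

    manifest.add_stage("done", n_rois=len(rois), flagged_frames=flagged)
    if outdir is not None:
        outdir = Path(outdir)
        export_results(outdir, bundle=bundle, rois=rois, config=cfg, seed=cfg.random_seed)
        manifest.save(outdir / "manifest.json")
    return ImagingResult(
        movie_pre=movie_pre,
        movie_registered=registered,
        dff=dff,
        projection=projection,
        rois=rois,
        bundle=bundle,
        shifts=shifts,
        manifest=manifest,
    )


@dataclass
class BehaviorResult:
    track: behavior.Track
    quality: dict
    epochs: behavior.BehaviorEpochs | None
    manifest: RunManifest


def run_behavior_pipeline(
    video,
    hsv_ranges,
    config: Config | None = None,
    epochs: behavior.BehaviorEpochs | None = None,
    min_blob_px: int = 10,
    max_gap_s: float = 0.5,
    outdir: str | Path | None = None,
) -> BehaviorResult:
    """Track markers, interpolate short gaps, report tracking quality."""
    cfg = config or Config()
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.random_seed)
    manifest.input_hashes["video"] = _hash_array(np.asarray(video.frames))
    try:
        track = behavior.track_markers(video, hsv_ranges, min_blob_px=min_blob_px)
    except Exception as exc:
        raise StageError("track_markers", exc) from exc
    manifest.add_stage("track_markers")
    track = behavior.interpolate_gaps(track, max_gap_s=max_gap_s)
    manifest.add_stage("interpolate_gaps")
    quality = behavior.quality_report(track)
    manifest.add_stage("quality_report", **{k: v for k, v in quality.items()
                                            if not isinstance(v, list)})
    if epochs is not None:
        manifest.add_stage("epochs", labels=epochs.labels)
    if outdir is not None:
        outdir = Path(outdir)
        export_results(outdir, track=track, epochs=epochs, config=cfg, seed=cfg.random_seed)
        manifest.save(outdir / "manifest.json")
    return BehaviorResult(track=track, quality=quality, epochs=epochs, manifest=manifest)


def run_joint_analysis(
    imaging: ImagingResult,
    behavior_result: BehaviorResult,
    offset_s: float = 0.0,
    bin_px: float = 20.0,
    min_occ_s: float = 0.2,
    triggers_s=None,
    pre_s: float = 1.0,
    post_s: float = 2.0,
) -> dict:
    """Spatial event maps, per-behavior rates, and optional sweeps."""
    from . import analysis

    bundle = imaging.bundle
    if bundle is None:
        raise ValueError("imaging pipeline produced no traces")
    n_frames = bundle.n_frames
    rate = bundle.frame_rate_hz
    mapped = behavior.map_track_to_imaging(
        behavior_result.track, rate, n_frames, offset_s
    )
    all_events = sorted(int(e) for ev in bundle.events for e in ev)
    out: dict[str, Any] = {}
    # arena extent approximated by the tracked marker span
    finite = np.isfinite(behavior_result.track.markers)
    arena_shape = (
        int(np.nanmax(behavior_result.track.markers[..., 0])) + 1 if finite.any() else 1,
        int(np.nanmax(behavior_result.track.markers[..., 1])) + 1 if finite.any() else 1,
    )
    out["spatial_map"] = analysis.spatial_event_map(
        all_events, mapped["position"], mapped["valid"], mapped["heading_deg"],
        rate, arena_shape, bin_px=bin_px, min_occ_s=min_occ_s,
    )
    if behavior_result.epochs is not None:
        frame_labels = behavior.map_epochs_to_imaging(
            behavior_result.epochs, rate, n_frames, offset_s
        )
        out["rates_by_behavior"] = analysis.event_rate_by_behavior(
            all_events, frame_labels, rate
        )
        out["raster"], out["population_rate"] = analysis.raster(
            bundle.events, rate, n_frames, frame_labels
        )
    if triggers_s:
        pop_trace = bundle.denoised.mean(axis=0)
        out["sweeps"] = analysis.sweep_align(pop_trace, triggers_s, pre_s, post_s, rate)
    else:
        logger.info("no triggers configured; sweeps skipped")
    return out
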