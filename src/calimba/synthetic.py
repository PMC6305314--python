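"""Ground-truthed synthetic fixtures: one-photon calcium movies and
marker behavior videos with the statistical structure the pipeline
assumes.

The movie generator emulates head-mounted single-photon data: strong
radial vignetting (GRIN-lens optics), low contrast, overlapping somata
with slow-decay AR(2) transients, spatially smooth temporally correlated
neuropil background, rigid jitter/drift, dust spots, and blank corrupted
frames.  The behavior generator renders colored marker discs moving on a
smoothed random-walk path over a textured arena.  Every generator is a
pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .behavior import BehaviorEpochs
from .io import BehaviorVideo, Movie
from .traces import Ar2Params, ar2_filter


@dataclass
class GroundTruth:
    """Everything a test needs to score the pipeline against the truth."""

    seed: int
    cell_masks: np.ndarray | None = None  # K x H x W bool
    spike_trains: np.ndarray | None = None  # K x T counts
    calcium: np.ndarray | None = None  # K x T
    ar2: list[Ar2Params] | None = None
    motion: np.ndarray | None = None  # T x 2 (dy, dx)
    corrupted_frames: list[int] = field(default_factory=list)
    dust_masks: np.ndarray | None = None
    vignette: np.ndarray | None = None
    path: np.ndarray | None = None  # T x 2 (row, col)
    heading_deg: np.ndarray | None = None
    marker_positions: np.ndarray | None = None  # T x n_markers x 2
    epochs: BehaviorEpochs | None = None


@dataclass
class MovieParams:
    """Study conditions for the synthetic one-photon movie.

    Defaults describe a typical desk-scale miniscope recording: a
    128 x 128 px field at 2.5 um/px (~320 um across), 10 Hz, 10 somata of
    8-20 px diameter firing sparsely (0.03 spikes/frame ~ 0.3 Hz), peak
    transient SNR 10 against the sensor noise, a few pixels of rigid
    jitter, one dust spot and two blank corrupted frames.
    """

    n_frames: int = 400
    height: int = 128
    width: int = 128
    frame_rate_hz: float = 10.0
    pixel_size_um: float = 2.5
    n_cells: int = 10
    cell_diameter_px: tuple[float, float] = (8.0, 20.0)
    spike_rate_per_frame: float = 0.03
    amplitude: float = 30.0
    snr: float = 10.0
    baseline: float = 100.0
    rise_tau_s: float = 0.08
    decay_tau_s: float = 0.6
    neuropil_scale: float = 0.3
    neuropil_sigma_px: float = 40.0  # out-of-focus background is much smoother than a soma
    motion_amplitude_px: float = 0.0
    motion_mode: Literal["jitter", "drift"] = "jitter"
    n_corrupted: int = 0
    n_dust: int = 0
    dust_radius_px: float = 6.0
    vignette_min_gain: float = 0.3
    min_center_distance_px: float | None = None
    vessels: bool = True


def _vignette(h: int, w: int, min_gain: float) -> np.ndarray:
    """Radial cosine-bell gain: 1 at center, ``min_gain`` at the corners."""
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    dist = np.hypot(rr - cy, cc - cx)
    dmax = np.hypot(cy, cx)
    return min_gain + (1.0 - min_gain) * 0.5 * (1.0 + np.cos(np.pi * dist / dmax))


def _gaussian_blob_mask(
    h: int, w: int, center: tuple[float, float], sig_r: float, sig_c: float,
    theta: float, level: float = 0.5
) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    g = np.exp(-0.5 * ((u / sig_r) ** 2 + (v / sig_c) ** 2))
    return g >= level


def _ar2_from_taus(rise_tau_s: float, decay_tau_s: float, fs: float) -> tuple[float, float]:
    d = float(np.exp(-1.0 / (decay_tau_s * fs)))
    r = float(np.exp(-1.0 / (rise_tau_s * fs)))
    return d + r, -d * r


def make_movie(params: MovieParams | None = None, seed: int = 0) -> tuple[Movie, GroundTruth]:
    """Render a ground-truthed synthetic one-photon movie.

    movie = motion( vignette * [baseline + somata + neuropil] + noise ),
    then dust pasted (dust sits on the optics, static in sensor
    coordinates) and corrupted frames blanked.
    """
    p = params or MovieParams()
    rng = np.random.default_rng(seed)
    T, H, W = p.n_frames, p.height, p.width

    # --- cell masks, rejection-sampled for a minimum center spacing
    masks = np.zeros((p.n_cells, H, W), dtype=bool)
    centers: list[tuple[float, float]] = []
    min_dist = (
        p.min_center_distance_px
        if p.min_center_distance_px is not None
        else 0.9 * p.cell_diameter_px[1]
    )
    margin = p.cell_diameter_px[1]
    attempts = 0
    k = 0
    while k < p.n_cells:
        attempts += 1
        if attempts > 2000:
            raise ValueError("cannot pack the requested cells at this spacing")
        center = (
            rng.uniform(margin, H - margin),
            rng.uniform(margin, W - margin),
        )
        if any(np.hypot(center[0] - a, center[1] - b) < min_dist for a, b in centers):
            continue
        dia = rng.uniform(*p.cell_diameter_px)
        aspect = rng.uniform(0.7, 1.0)
        sig = dia / 2.355  # FWHM -> sigma
        masks[k] = _gaussian_blob_mask(H, W, center, sig, sig * aspect, rng.uniform(0, np.pi))
        if masks[k].sum() < 5:
            continue
        centers.append(center)
        k += 1

    # --- spikes and AR(2) calcium per cell
    g1, g2 = _ar2_from_taus(p.rise_tau_s, p.decay_tau_s, p.frame_rate_hz)
    spikes = rng.poisson(p.spike_rate_per_frame, size=(p.n_cells, T)).astype(float)
    if p.n_cells:
        calcium = np.stack([ar2_filter(s, g1, g2) for s in spikes])
    else:
        calcium = np.zeros((0, T))
    peak = ar2_filter(np.eye(1, T, 0).ravel(), g1, g2).max() if T else 1.0

    # --- scene: baseline + somata + smooth neuropil (+ static vessels)
    scene = np.full((T, H, W), p.baseline)
    soma_gain = p.amplitude / peak  # one spike peaks at `amplitude` above baseline
    for k in range(p.n_cells):
        scene[:, masks[k]] += soma_gain * calcium[k][:, None]
    if p.neuropil_scale > 0:
        # coarse spatiotemporal noise at the neuropil spatial scale
        gh = max(2, int(np.ceil(H / p.neuropil_sigma_px)))
        gw = max(2, int(np.ceil(W / p.neuropil_sigma_px)))
        bg_t = ndimage.gaussian_filter1d(
            rng.normal(size=(T, gh, gw)), sigma=3.0, axis=0
        )
        bg = ndimage.zoom(bg_t, (1, H / gh, W / gw), order=3)
        bg *= p.amplitude * p.neuropil_scale / max(bg.std(), 1e-9)
        # neuropil also carries a diluted, blurred copy of the summed cell
        # activity so the scaled-subtraction correction is exercised
        footprint = ndimage.gaussian_filter(
            masks.sum(axis=0).astype(float) * soma_gain, p.neuropil_sigma_px
        )
        mean_cal = calcium.mean(axis=0) if p.n_cells else np.zeros(T)
        scene += bg + p.neuropil_scale * footprint[None] * mean_cal[:, None, None]
    if p.vessels:
        vessels = np.zeros((H, W))
        for _ in range(3):
            r0 = rng.uniform(0.2 * H, 0.8 * H)
            amplitude = rng.uniform(0.05, 0.12) * p.baseline
            freq = rng.uniform(1.0, 2.5)
            phase = rng.uniform(0, 2 * np.pi)
            cc = np.arange(W)
            rows = (r0 + 0.15 * H * np.sin(2 * np.pi * freq * cc / W + phase)).astype(int)
            for c, r in enumerate(rows):
                if 1 <= r < H - 1:
                    vessels[r - 1 : r + 2, c] -= amplitude
        scene += vessels[None]

    vignette = _vignette(H, W, p.vignette_min_gain)
    noise_sigma = p.amplitude / p.snr if p.snr > 0 else 0.0
    frames = scene * vignette[None] + rng.normal(0.0, noise_sigma, size=(T, H, W))

    # --- rigid motion
    motion = np.zeros((T, 2))
    if p.motion_amplitude_px > 0:
        if p.motion_mode == "jitter":
            motion = rng.uniform(-p.motion_amplitude_px, p.motion_amplitude_px, size=(T, 2))
            motion[0] = 0.0
        else:  # linear drift up to the amplitude
            ramp = np.linspace(0.0, p.motion_amplitude_px, T)
            direction = rng.uniform(-1.0, 1.0, size=2)
            direction /= max(np.linalg.norm(direction), 1e-9)
            motion = ramp[:, None] * direction[None]
        for t in range(T):
            if motion[t, 0] or motion[t, 1]:
                frames[t] = ndimage.shift(frames[t], motion[t], order=1, mode="nearest")

    # --- dust (static in sensor coordinates, pasted after motion)
    dust_masks = None
    if p.n_dust > 0:
        dust_masks = np.zeros((p.n_dust, H, W), dtype=bool)
        rr, cc = np.mgrid[0:H, 0:W]
        for i in range(p.n_dust):
            cy = rng.uniform(0.2 * H, 0.8 * H)
            cx = rng.uniform(0.2 * W, 0.8 * W)
            dust_masks[i] = np.hypot(rr - cy, cc - cx) <= p.dust_radius_px
            frames[:, dust_masks[i]] *= 0.25
    # --- corrupted (blank) frames, never frame 0
    corrupted: list[int] = []
    if p.n_corrupted > 0:
        corrupted = sorted(
            int(i) for i in rng.choice(np.arange(1, T), size=p.n_corrupted, replace=False)
        )
        for t in corrupted:
            frames[t] = rng.normal(0.0, noise_sigma + 1e-3, size=(H, W))

    frames = np.clip(frames, 0.0, None)
    movie = Movie(
        data=frames,
        frame_rate_hz=p.frame_rate_hz,
        pixel_size_um=p.pixel_size_um,
        origin=f"synthetic(seed={seed})",
    )
    truth = GroundTruth(
        seed=seed,
        cell_masks=masks,
        spike_trains=spikes,
        calcium=calcium,
        ar2=[Ar2Params(g1=g1, g2=g2)] * p.n_cells,
        motion=motion,
        corrupted_frames=corrupted,
        dust_masks=dust_masks,
        vignette=vignette,
    )
    return movie, truth


@dataclass
class BehaviorVideoParams:
    """Study conditions for the synthetic arena video.

    A 200 x 200 px top-down arena at 30 Hz with one or two 10-px marker
    discs (red head marker, blue tail marker) on a smoothed random-walk
    path; an alternating walk/rest epoch schedule is returned as ground
    truth.
    """

    n_frames: int = 200
    height: int = 200
    width: int = 200
    frame_rate_hz: float = 30.0
    n_markers: int = 2
    marker_diameter_px: float = 10.0
    marker_separation_px: float = 14.0
    marker_colors: tuple[tuple[int, int, int], ...] = ((220, 30, 30), (30, 60, 220))
    background_gray: int = 120
    texture_amplitude: int = 15
    step_sigma_px: float = 3.0
    smooth_sigma_frames: float = 5.0
    path_mode: Literal["walk", "sine", "static"] = "walk"
    epoch_period_s: float = 2.0


def make_behavior_video(
    params: BehaviorVideoParams | None = None, seed: int = 0
) -> tuple[BehaviorVideo, GroundTruth]:
    """Render a marker video plus ground-truth path, heading and epochs."""
    p = params or BehaviorVideoParams()
    if p.marker_diameter_px >= min(p.height, p.width) / 2:
        raise ValueError("markers larger than the arena")
    rng = np.random.default_rng(seed)
    T, H, W = p.n_frames, p.height, p.width
    margin = p.marker_diameter_px + p.marker_separation_px + 2

    if p.path_mode == "static":
        path = np.tile(np.array([[H / 2.0, W / 2.0]]), (T, 1))
    elif p.path_mode == "sine":
        t = np.arange(T)
        path = np.stack(
            [
                H / 2.0 + (H / 2.0 - margin) * np.sin(2 * np.pi * t / T),
                W / 2.0 + (W / 2.0 - margin) * np.cos(2 * np.pi * t / T),
            ],
            axis=1,
        )
    else:
        steps = rng.normal(0.0, p.step_sigma_px, size=(T, 2))
        path = np.cumsum(steps, axis=0)
        path = ndimage.gaussian_filter1d(path, p.smooth_sigma_frames, axis=0)
        path -= path.mean(axis=0)
        span = np.abs(path).max(axis=0)
        scale = np.minimum(1.0, (np.array([H, W]) / 2.0 - margin) / np.maximum(span, 1e-9))
        path = path * scale + np.array([H / 2.0, W / 2.0])

    # heading from the path tangent (y-up image convention)
    grad = np.gradient(path, axis=0)
    heading_deg = np.degrees(np.arctan2(-grad[:, 0], grad[:, 1])) % 360.0

    # markers straddle the position along the heading axis; marker 1 sits
    # behind and marker 2 ahead, so the m1 -> m2 vector equals the heading
    theta = np.radians(heading_deg)
    offsets = np.stack([-np.sin(theta), np.cos(theta)], axis=1)  # (d_row, d_col)
    half = p.marker_separation_px / 2.0
    marker_positions = np.zeros((T, p.n_markers, 2))
    if p.n_markers == 1:
        marker_positions[:, 0] = path
    else:
        marker_positions[:, 0] = path - half * offsets
        marker_positions[:, 1] = path + half * offsets

    texture = rng.integers(
        -p.texture_amplitude, p.texture_amplitude + 1, size=(H, W)
    )
    base = np.clip(p.background_gray + texture, 0, 255).astype(np.uint8)
    base_rgb = np.repeat(base[:, :, None], 3, axis=-1)
    frames = np.broadcast_to(base_rgb, (T, H, W, 3)).copy()

    rr, cc = np.mgrid[0:H, 0:W]
    radius = p.marker_diameter_px / 2.0
    for t in range(T):
        for m in range(p.n_markers):
            cy, cx = marker_positions[t, m]
            disc = np.hypot(rr - cy, cc - cx) <= radius
            frames[t][disc] = p.marker_colors[m]

    video = BehaviorVideo(frames=frames, frame_rate_hz=p.frame_rate_hz)

    duration = T / p.frame_rate_hz
    intervals = []
    label_cycle = ["walk", "rest"]
    start = 0.0
    i = 0
    while start < duration:
        end = min(start + p.epoch_period_s, duration)
        if end > start:
            intervals.append((label_cycle[i % 2], start, end))
        start = end
        i += 1
    epochs = BehaviorEpochs(intervals=intervals)

    truth = GroundTruth(
        seed=seed,
        path=path,
        heading_deg=heading_deg,
        marker_positions=marker_positions,
        epochs=epochs,
    )
    return video, truth


@dataclass
class TraceParams:
    """Unit-fixture trace: AR(2) convolution of Poisson spikes plus an
    exponential bleaching trend and white noise."""

    n_frames: int = 3000
    frame_rate_hz: float = 10.0
    g1: float = 1.7
    g2: float = -0.712
    spike_rate_per_frame: float = 0.02
    amplitude: float = 1.0
    noise_sigma: float = 0.1
    bleach_amplitude: float = 0.0
    bleach_tau_s: float = 120.0


def make_trace(
    params: TraceParams | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, Ar2Params]:
    """Generate (trace, spikes, ar2) for the trace-level fixtures."""
    p = params or TraceParams()
    ar2 = Ar2Params(g1=p.g1, g2=p.g2, noise_sigma=p.noise_sigma)  # validates stability
    rng = np.random.default_rng(seed)
    spikes = p.amplitude * rng.poisson(p.spike_rate_per_frame, size=p.n_frames)
    calcium = ar2_filter(spikes.astype(float), p.g1, p.g2)
    t = np.arange(p.n_frames) / p.frame_rate_hz
    trend = p.bleach_amplitude * np.exp(-t / p.bleach_tau_s)
    trace = calcium + trend + rng.normal(0.0, p.noise_sigma, size=p.n_frames)
    return trace, spikes.astype(float), ar2
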