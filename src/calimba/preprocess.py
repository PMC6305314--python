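"""Pre-processing: dust removal, corrupted-frame repair, down-sampling,
flat-field correction.

Corrupted frames (blank or noise-distorted frames from tether glitches)
are detected with the amplitude-threshold rule used for extracellular
spike detection, applied to the temporal difference of the per-frame mean
intensity: ``thr = multiplier * median(|dI| / mad_const)`` with defaults
``multiplier=5`` and ``mad_const=0.6745`` (the MAD-to-sigma constant for
Gaussian noise).  Frames whose |dI| exceeds thr are replaced with the
preceding good frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.transform import resize

from .io import CalimbaError, Movie


class DustRingError(CalimbaError, ValueError):
    """Dust mask leaves no ring pixels (e.g. covers the whole frame)."""


class AllFramesCorruptError(CalimbaError, ValueError):
    """Every frame was flagged corrupted; nothing to copy from."""


@dataclass
class FrameStats:
    """Per-frame mean intensity, its temporal difference, and the threshold."""

    mean_intensity: np.ndarray  # I-bar, length T
    diff: np.ndarray  # delta I-bar, length T-1
    thr: float

    def __post_init__(self) -> None:
        if len(self.diff) != len(self.mean_intensity) - 1:
            raise ValueError("diff must have length len(mean_intensity) - 1")
        if self.thr < 0:
            raise ValueError("thr must be non-negative")


@dataclass
class DustRegion:
    """Binary mask of a dust/abnormality region plus the ring width used to fill it."""

    mask: np.ndarray
    ring_width_px: int = 8

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("dust mask must be 2-D")
        if not self.mask.any():
            raise ValueError("dust mask is empty")
        if self.ring_width_px < 1:
            raise ValueError("ring_width_px must be >= 1")


def ring_mask(mask: np.ndarray, ring_width_px: int) -> np.ndarray:
    """Annulus of ``ring_width_px`` thickness around ``mask``, clipped to frame.

    Built by morphological dilation with a disc structuring element of
    radius ``ring_width_px``, minus the mask itself.  Edge-touching
    regions keep only in-frame ring pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    dilated = ndimage.binary_dilation(mask, structure=disk(ring_width_px))
    ring = dilated & ~mask
    if not ring.any():
        raise DustRingError("no ring pixels around mask (mask covers the frame?)")
    return ring


def remove_dust(movie: Movie, region: DustRegion) -> Movie:
    """Fill each dust component with the mean of its surrounding ring, per frame.

    Multi-component masks are filled per 4-connected component, each with
    the mean over its own ring.  Pixels outside the mask are untouched.
    """
    mask = region.mask
    if mask.shape != movie.frame_shape:
        raise ValueError("dust mask shape does not match movie frames")
    labels, n = ndimage.label(mask)
    data = movie.data.copy()
    for lab in range(1, n + 1):
        comp = labels == lab
        ring = ring_mask(comp, region.ring_width_px)
        # vectorized over time: mean of ring pixels per frame
        fill = data[:, ring].mean(axis=1)
        data[:, comp] = fill[:, None]
    return movie.with_data(data)


def compute_corrupt_threshold(
    movie: Movie, multiplier: float = 5.0, mad_const: float = 0.6745
) -> FrameStats:
    """Threshold on |dI-bar| for corrupted-frame detection.

    ``thr = multiplier * median(|dI| / mad_const)``; the median of
    |dI|/0.6745 is a robust estimate of the noise SD of the frame-to-frame
    intensity difference, so thr sits ``multiplier`` noise-SDs out.
    """
    if movie.n_frames < 3:
        raise ValueError("need at least 3 frames to estimate the threshold")
    mean_intensity = movie.data.mean(axis=(1, 2))
    diff = np.diff(mean_intensity)
    thr = float(multiplier * np.median(np.abs(diff) / mad_const))
    return FrameStats(mean_intensity=mean_intensity, diff=diff, thr=thr)


def detect_corrupt_frames(movie: Movie, stats: FrameStats) -> list[int]:
    """Frames t >= 1 with |dI_t| strictly above thr, ascending.

    A tie with thr is not flagged (the rule is "exceeding").  Frame 0 has
    no preceding frame and is never flagged by this rule.
    """
    if len(stats.mean_intensity) != movie.n_frames:
        raise ValueError("stats were computed on a different movie")
    flagged = np.nonzero(np.abs(stats.diff) > stats.thr)[0] + 1
    return [int(i) for i in flagged]


def replace_frames(movie: Movie, indices: Sequence[int]) -> Movie:
    """Replace each flagged frame with the nearest preceding good frame.

    Runs of consecutive flagged frames all receive the last good frame
    before the run.  Flagged frames at the start of the movie are copied
    from the nearest following good frame instead.  Returns a movie whose
    ``replaced_frames`` attribute lists the indices that were overwritten,
    so downstream steps can ignore duplicated frames if configured.
    """
    bad = set(int(i) for i in indices)
    if not bad:
        out = movie.with_data(movie.data.copy())
        out.replaced_frames = []
        return out
    if any(i < 0 or i >= movie.n_frames for i in bad):
        raise IndexError("frame index out of range")
    if len(bad) == movie.n_frames:
        raise AllFramesCorruptError("all frames flagged corrupted")
    data = movie.data.copy()
    last_good: int | None = None
    pending: list[int] = []  # leading bad frames before any good one
    for t in range(movie.n_frames):
        if t in bad:
            if last_good is None:
                pending.append(t)
            else:
                data[t] = data[last_good]
        else:
            if pending:
                for p in pending:
                    data[p] = data[t]
                pending = []
            last_good = t
    out = movie.with_data(data)
    out.replaced_frames = sorted(bad)
    return out


def downsample(
    movie: Movie, factor: float = 0.40, trigger_width_px: int = 100
) -> Movie:
    """Spatially down-sample wide movies to ``factor`` of their size.

    Movies whose width is at most ``trigger_width_px`` are returned
    unchanged (already near the optical resolution limit).  Resizing is
    anti-aliased; ``pixel_size_um`` is rescaled by the actual width
    ratio.  The time dimension is never resampled.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    t, h, w = movie.data.shape
    if w <= trigger_width_px or factor == 1.0:
        return movie.with_data(movie.data.copy())
    new_h = max(1, round(factor * h))
    new_w = max(1, round(factor * w))
    out = resize(
        movie.data,
        (t, new_h, new_w),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return movie.with_data(out, pixel_size_um=movie.pixel_size_um * w / new_w)


def _log_poly_gain(mean_img: np.ndarray, degree: int, eps: float) -> np.ndarray:
    h, w = mean_img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    yy = 2.0 * yy / max(h - 1, 1) - 1.0
    xx = 2.0 * xx / max(w - 1, 1) - 1.0
    terms = []
    for deg in range(degree + 1):
        for i in range(deg + 1):
            terms.append(xx**i * yy ** (deg - i))
    A = np.stack([t.ravel() for t in terms], axis=1)
    coef, *_ = np.linalg.lstsq(A, np.log(np.maximum(mean_img, eps)).ravel(), rcond=None)
    return np.exp(A @ coef).reshape(h, w)


def flatfield_correct(
    movie: Movie,
    method: str = "poly",
    blur_sigma_px: float | None = None,
    poly_degree: int = 4,
    eps: float = 1e-12,
) -> Movie:
    """Divide each frame by a smooth estimate of the static gain field.

    Removes illumination vignetting (strong toward the borders with
    GRIN-lens optics) while preserving per-pixel temporal dynamics
    exactly (each pixel's series is rescaled by one constant).

    ``method='poly'`` (default) fits a low-order 2-D polynomial to the
    log of the temporal-mean image; a least-squares fit in log space is a
    linear projection, so the correction is idempotent and tracks the
    smooth vignette without the curvature bias of a wide blur.
    ``method='blur'`` divides by the heavily Gaussian-blurred mean image
    (``blur_sigma_px`` default 10% of the smaller frame dimension) —
    large enough to dwarf somata (~10-20 px).  Output is dimensionless
    around 1.
    """
    mean_img = movie.data.mean(axis=0)
    if method == "poly":
        gain = _log_poly_gain(mean_img, poly_degree, eps)
    elif method == "blur":
        if blur_sigma_px is None:
            blur_sigma_px = 0.1 * min(movie.frame_shape)
        gain = ndimage.gaussian_filter(mean_img, sigma=blur_sigma_px)
    else:
        raise ValueError(f"unknown flat-field method {method!r}")
    gain = np.maximum(gain, eps)
    return movie.with_data(movie.data / gain[None])
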