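"""Rigid translation correction for fluorescence movies.

Two estimators are provided: upsampled-DFT subpixel phase correlation and
an iterative translation-only Lucas-Kanade solver.  Both support matching
on a rectangular seed region (e.g. a blood vessel) or the full frame, and
a static reference (frame 0 or the temporal mean) or a dynamic reference
(each frame against its aligned predecessor, shifts accumulated — useful
because the slow decay of GCaMP fluorescence keeps consecutive frames
similar).  Only translation is modeled; rotation is a documented
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .io import CalimbaError, Movie


class SeedRegionError(CalimbaError, ValueError):
    """Seed region invalid: outside the frame, too small, or constant."""


class EmptyCropError(CalimbaError, ValueError):
    """crop_to_valid would remove every pixel."""


Seed = tuple[int, int, int, int]  # (row, col, height, width)


@dataclass
class ShiftSeries:
    """Per-frame rigid shifts ``(dy, dx)`` in pixels.

    ``dy[t], dx[t]`` is the estimated displacement of frame t relative to
    the reference; frames are corrected by resampling at the negated
    shift.
    """

    dy: np.ndarray
    dx: np.ndarray
    reference_mode: Literal["static", "dynamic"] = "static"
    seed: Seed | None = None

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx must have equal length")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("shifts must be finite")

    def __len__(self) -> int:
        return len(self.dy)

    def max_abs(self) -> float:
        return float(max(np.abs(self.dy).max(), np.abs(self.dx).max()))


def _validate_seed(seed: Seed | None, frame_shape: tuple[int, int],
                   min_size: int = 16) -> Seed | None:
    if seed is None:
        return None
    r, c, h, w = seed
    H, W = frame_shape
    if h < min_size or w < min_size:
        raise SeedRegionError(f"seed must be at least {min_size}x{min_size} px")
    if r < 0 or c < 0 or r + h > H or c + w > W:
        raise SeedRegionError("seed region extends outside the frame")
    return seed


def default_seed(frame_shape: tuple[int, int], size: int = 40) -> Seed:
    """Centered square seed region, 40x40 px by default."""
    H, W = frame_shape
    size = min(size, H, W)
    return ((H - size) // 2, (W - size) // 2, size, size)


def _crop(img: np.ndarray, seed: Seed | None) -> np.ndarray:
    if seed is None:
        return img
    r, c, h, w = seed
    return img[r : r + h, c : c + w]


def _check_not_constant(patch: np.ndarray) -> None:
    if np.ptp(patch) == 0:
        raise SeedRegionError("seed region is constant; cannot register on it")


def apply_shift(frame: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Resample a frame at the negated shift (bilinear, edge-value fill)."""
    return ndimage.shift(frame, (-dy, -dx), order=1, mode="nearest")


def _register(
    movie: Movie,
    estimate: "callable",
    seed: Seed | None,
    mode: Literal["static", "dynamic"],
    static_reference: Literal["first", "mean"],
) -> tuple[Movie, ShiftSeries]:
    data = movie.data
    T = data.shape[0]
    seed = _validate_seed(seed, movie.frame_shape)
    dy = np.zeros(T)
    dx = np.zeros(T)
    out = np.empty_like(data)

    if mode == "static":
        ref_img = data[0] if static_reference == "first" else data.mean(axis=0)
        ref_patch = _crop(ref_img, seed)
        _check_not_constant(ref_patch)
        for t in range(T):
            dy[t], dx[t] = estimate(ref_patch, _crop(data[t], seed))
            out[t] = apply_shift(data[t], dy[t], dx[t])
    elif mode == "dynamic":
        out[0] = data[0]
        prev_aligned = data[0]
        for t in range(1, T):
            ref_patch = _crop(prev_aligned, seed)
            _check_not_constant(ref_patch)
            # incremental shift of the raw frame vs. the aligned predecessor
            sdy, sdx = estimate(ref_patch, _crop(data[t], seed))
            dy[t], dx[t] = sdy, sdx
            out[t] = apply_shift(data[t], dy[t], dx[t])
            prev_aligned = out[t]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    shifts = ShiftSeries(dy=dy, dx=dx, reference_mode=mode, seed=seed)
    return movie.with_data(out), shifts


def register_subpixel(
    movie: Movie,
    seed: Seed | None = None,
    mode: Literal["static", "dynamic"] = "static",
    upsample: int = 20,
    static_reference: Literal["first", "mean"] = "first",
) -> tuple[Movie, ShiftSeries]:
    """Phase-correlation registration with 1/``upsample`` px precision.

    Uses the upsampled cross-correlation (matrix-multiply DFT) method:
    the correlation peak is located to integer precision and refined in a
    locally upsampled neighborhood.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")

    def estimate(ref: np.ndarray, cur: np.ndarray) -> tuple[float, float]:
        # spectral whitening ("phase" normalization) keeps the peak sharp
        # even when low-contrast frames meet a blurry reference
        shift, _, _ = phase_cross_correlation(
            ref, cur, upsample_factor=upsample, normalization="phase"
        )
        # phase_cross_correlation returns the shift that moves cur onto ref;
        # our convention: (dy, dx) is the displacement of cur relative to ref.
        return -float(shift[0]), -float(shift[1])

    return _register(movie, estimate, seed, mode, static_reference)


def register_lucas_kanade(
    movie: Movie,
    seed: Seed | None = None,
    mode: Literal["static", "dynamic"] = "static",
    max_iter: int = 50,
    tol: float = 0.01,
    smooth_sigma: float = 1.0,
    static_reference: Literal["first", "mean"] = "first",
) -> tuple[Movie, ShiftSeries]:
    """Iterative gradient-based (Lucas-Kanade) translation registration.

    Single-level, translation-only warp.  Images are pre-smoothed with a
    Gaussian (sigma ``smooth_sigma``) for gradient stability; iterations
    stop when the update falls below ``tol`` pixels or ``max_iter`` is
    reached.  Works best on data with visible local features such as
    blood vessels.
    """

    def estimate(ref: np.ndarray, cur: np.ndarray) -> tuple[float, float]:
        ref_s = ndimage.gaussian_filter(ref, smooth_sigma)
        cur_s = ndimage.gaussian_filter(cur, smooth_sigma)
        gy, gx = np.gradient(ref_s)
        # normal equations of the linearized SSD; borders excluded where
        # the shifted image is extrapolated
        A = np.array(
            [[np.sum(gy * gy), np.sum(gy * gx)], [np.sum(gy * gx), np.sum(gx * gx)]]
        )
        if np.linalg.cond(A) > 1e12:
            raise SeedRegionError("degenerate gradients in seed region")
        dy = dx = 0.0
        for _ in range(max_iter):
            warped = ndimage.shift(cur_s, (-dy, -dx), order=1, mode="nearest")
            err = warped - ref_s
            b = -np.array([np.sum(gy * err), np.sum(gx * err)])
            step = np.linalg.solve(A, b)
            dy += step[0]
            dx += step[1]
            if np.hypot(*step) < tol:
                break
        return dy, dx

    return _register(movie, estimate, seed, mode, static_reference)


def crop_to_valid(movie: Movie, shifts: ShiftSeries) -> Movie:
    """Crop margins set by the extreme shifts so no extrapolated pixel remains.

    A frame shifted by ``+dy`` is resampled from rows below it, so its
    top ``dy`` rows are extrapolated; the maximum positive dy over frames
    is removed from the top, the maximum negative dy from the bottom, and
    likewise for columns.
    """
    if len(shifts) != movie.n_frames:
        raise ValueError("shift series length does not match movie")
    top = int(np.ceil(max(0.0, float(np.max(shifts.dy)))))
    bottom = int(np.ceil(max(0.0, float(-np.min(shifts.dy)))))
    left = int(np.ceil(max(0.0, float(np.max(shifts.dx)))))
    right = int(np.ceil(max(0.0, float(-np.min(shifts.dx)))))
    H, W = movie.frame_shape
    if top + bottom >= H or left + right >= W:
        raise EmptyCropError("shift extrema would crop away the entire frame")
    data = movie.data[:, top : H - bottom, left : W - right].copy()
    return movie.with_data(data)


def alignment_quality(
    movie: Movie, blur_sigma_px: float | None = None
) -> dict:
    """Per-frame Pearson correlation to the mean image, after a fixed protocol.

    Protocol: flat-field correct (divide by the heavily blurred mean
    image), crop to the middle 80% of each dimension, min-max normalize
    each frame to [0, 1], then correlate every frame with the mean of the
    processed series.  Returns ``{"r": per-frame array (NaN where a frame
    is constant), "median_r": float, "constant_frames": list}``.
    """
    from .preprocess import flatfield_correct

    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames")
    # the printed protocol: divide by the heavily blurred mean image
    ff = flatfield_correct(movie, method="blur", blur_sigma_px=blur_sigma_px).data
    T, H, W = ff.shape
    mh, mw = int(round(0.1 * H)), int(round(0.1 * W))
    cropped = ff[:, mh : H - mh or None, mw : W - mw or None]

    lo = cropped.min(axis=(1, 2), keepdims=True)
    rng = np.ptp(cropped, axis=(1, 2)).reshape(-1, 1, 1)
    constant = rng[:, 0, 0] == 0
    safe_rng = np.where(rng == 0, 1.0, rng)
    norm = (cropped - lo) / safe_rng

    mean_img = norm.mean(axis=0)
    flat = norm.reshape(T, -1)
    mflat = mean_img.ravel()
    fc = flat - flat.mean(axis=1, keepdims=True)
    mc = mflat - mflat.mean()
    denom = np.linalg.norm(fc, axis=1) * np.linalg.norm(mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc @ mc) / denom
    r[constant | (denom == 0)] = np.nan
    return {
        "r": r,
        "median_r": float(np.nanmedian(r)),
        "constant_frames": [int(i) for i in np.nonzero(constant)[0]],
    }
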