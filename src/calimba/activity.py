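"""dF/F conversion and std-weighted maximum-intensity projection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import Movie


@dataclass
class DffMovie:
    """Relative fluorescence change ``(F_t - Fbar) / Fbar`` per pixel.

    ``data`` is dimensionless with per-pixel temporal mean 0 by
    construction; ``mean_image`` is the baseline Fbar in the original
    fluorescence units.
    """

    data: np.ndarray
    mean_image: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("dF/F data must be 3-D")
        if self.mean_image.shape != self.data.shape[1:]:
            raise ValueError("mean_image shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


def delta_f_over_f(movie: Movie, eps: float = 1e-12) -> DffMovie:
    """Per-pixel dF/F with the full-series temporal mean as baseline F-bar.

    ``out_t = (F_t - Fbar) / Fbar``.  The baseline is guarded by ``eps``
    against zero-mean pixels; the result is scale invariant (multiplying
    the movie by k > 0 leaves dF/F unchanged).
    """
    mean_image = movie.data.mean(axis=0)
    baseline = np.maximum(mean_image, eps)
    data = (movie.data - mean_image[None]) / baseline[None]
    return DffMovie(
        data=data,
        mean_image=mean_image,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_size_um=movie.pixel_size_um,
    )


def max_projection_weighted(
    source: Movie | DffMovie,
    weighting: Literal["max_std", "max", "std"] = "max_std",
) -> np.ndarray:
    """Cell-highlighting projection: per-pixel max over time, std-weighted.

    The region of a cell is brightest during a calcium event and also
    fluctuates most, so weighting the temporal maximum by the temporal
    standard deviation suppresses static bright structures (vessels,
    vignette remnants).  The result is min-max normalized to [0, 1];
    a constant movie yields an all-zero image.
    """
    data = source.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    # sort each pixel's series so the result is exactly invariant to
    # frame order (float reductions are order-dependent otherwise)
    data = np.sort(data, axis=0)
    if weighting == "max_std":
        proj = data.max(axis=0) * data.std(axis=0)
    elif weighting == "max":
        proj = data.max(axis=0)
    elif weighting == "std":
        proj = data.std(axis=0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        return np.zeros_like(proj)
    return (proj - lo) / (hi - lo)
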