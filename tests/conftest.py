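"""Shared fixtures: tiny deterministic movies and images."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from calimba.io import Movie


def textured_frame(shape=(64, 64), seed=0, smooth=1.5):
    """Smooth random texture with positive offset, good for registration."""
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.normal(size=shape), smooth)
    return img - img.min() + 1.0


def make_movie(data, frame_rate=10.0, pixel_size=2.5) -> Movie:
    return Movie(np.asarray(data, dtype=float), frame_rate, pixel_size)


@pytest.fixture
def constant_movie() -> Movie:
    return make_movie(np.full((6, 32, 32), 7.0))


@pytest.fixture
def textured_movie() -> Movie:
    frame = textured_frame()
    return make_movie(np.stack([frame] * 5))


@pytest.fixture
def disc_mask():
    def _make(shape, center, radius):
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return np.hypot(rr - center[0], cc - center[1]) <= radius

    return _make
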