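"""Figure helpers, kept strictly out of the computational API.

Matplotlib is imported lazily so the analysis stack works without it.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_traces_with_events(bundle, roi_indices=None, ax=None, spacing: float = 1.0):
    """Stacked raw (gray) and denoised (colored) traces with event dots."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    idx = roi_indices if roi_indices is not None else range(bundle.n_rois)
    t = np.arange(bundle.n_frames) / bundle.frame_rate_hz
    for row, i in enumerate(idx):
        offset = row * spacing
        ax.plot(t, bundle.detrended[i] + offset, color="0.6", lw=0.6)
        if bundle.denoised is not None:
            ax.plot(t, bundle.denoised[i] + offset, color="C0", lw=0.9)
        if bundle.events is not None and len(bundle.events[i]):
            ev = bundle.events[i]
            ax.plot(t[ev], bundle.denoised[i][ev] + offset, "k.", ms=5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROI (offset)")
    return ax


def plot_rate_map(spatial_map, ax=None, arrows: bool = True):
    """Event-rate heatmap with orientation arrows at event positions."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(spatial_map.rate_map, origin="upper", cmap="viridis")
    plt.colorbar(im, ax=ax, label="event rate (Hz)")
    if arrows:
        for r, c, hd in spatial_map.event_points:
            if np.isfinite(hd):
                dr = -np.sin(np.radians(hd))
                dc = np.cos(np.radians(hd))
                ax.annotate(
                    "",
                    xy=((c + 5 * dc) / spatial_map.bin_px, (r + 5 * dr) / spatial_map.bin_px),
                    xytext=(c / spatial_map.bin_px, r / spatial_map.bin_px),
                    arrowprops=dict(arrowstyle="->", color="w", lw=0.8),
                )
    return ax


def plot_sweeps(stack, ax=None):
    """Stacked single-trial rows with the mean +/- SEM trace below."""
    plt = _plt()
    if ax is None:
        _, (ax_top, ax) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
        ax_top.imshow(
            stack.trials,
            aspect="auto",
            extent=[stack.times_s[0], stack.times_s[-1], stack.n_trials, 0],
        )
        ax_top.set_ylabel("trial")
    ax.plot(stack.times_s, stack.mean, color="C0")
    ax.fill_between(
        stack.times_s, stack.mean - stack.sem, stack.mean + stack.sem,
        alpha=0.3, color="C0",
    )
    ax.axvline(0, color="k", ls=":")
    ax.set_xlabel("time from trigger (s)")
    ax.set_ylabel("mean +/- SEM")
    return ax
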