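"""Trace extraction, neuropil correction, detrending, and AR(2) OASIS
deconvolution into denoised traces and discrete calcium events.

The processing chain per ROI is: mean trace over the mask (raw), mean
over a 20-um surrounding annulus (neuropil), subtraction of the scaled
neuropil (``corrected = raw - r * neuropil`` with r = 0.7 by default),
bleaching removal (running-percentile or linear detrend), and sparse
non-negative deconvolution under second-order autoregressive indicator
dynamics (fast rise, slow decay) using the OASIS online active-set
method.  Event times are derived from the deconvolved activity with a
MAD-based threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, signal
from skimage.morphology import disk

from .activity import DffMovie
from .cells import RoiSet
from .io import CalimbaError, InconsistentLengthError, Movie


class EmptyNeuropilRingError(CalimbaError, ValueError):
    """Neuropil annulus has no pixels left after exclusions."""


class UnstableAr2Error(CalimbaError, ValueError):
    """AR(2) coefficients describe an unstable (divergent) kernel."""


@dataclass
class Ar2Params:
    """Second-order autoregressive indicator kinetics.

    The calcium impulse response obeys
    ``c_t = g1 * c_{t-1} + g2 * c_{t-2} + s_t``; stability requires both
    roots of ``z^2 - g1 z - g2`` inside the unit circle.  ``noise_sigma``
    is the white-noise SD of the observed trace.
    """

    g1: float
    g2: float
    noise_sigma: float = 0.0
    s_min: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        d, r = self.roots
        if max(abs(d), abs(r)) >= 1.0:
            raise UnstableAr2Error(f"g=({self.g1}, {self.g2}) has root modulus >= 1")

    @property
    def roots(self) -> tuple[complex, complex]:
        disc = self.g1 * self.g1 + 4.0 * self.g2
        sq = np.sqrt(complex(disc))
        return (self.g1 + sq) / 2.0, (self.g1 - sq) / 2.0


@dataclass
class TraceBundle:
    """Per-ROI series on the imaging timebase.

    All arrays are (n_rois, T); ``events`` holds one sorted integer index
    array per ROI.  Stages not yet computed are None.
    """

    raw: np.ndarray
    neuropil: np.ndarray | None = None
    corrected: np.ndarray | None = None
    detrended: np.ndarray | None = None
    denoised: np.ndarray | None = None
    spikes: np.ndarray | None = None
    events: list[np.ndarray] | None = None
    frame_rate_hz: float = 1.0
    ar2: list[Ar2Params] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.raw.shape[-1]
        for kind in ("neuropil", "corrected", "detrended", "denoised", "spikes"):
            series = getattr(self, kind)
            if series is not None and series.shape[-1] != t:
                raise InconsistentLengthError(f"{kind} length != raw length")
        if self.spikes is not None and np.any(self.spikes < 0):
            raise ValueError("spikes must be non-negative")

    @property
    def n_rois(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[-1]


def neuropil_ring_masks(
    rois: RoiSet,
    pixel_size_um: float,
    ring_width_um: float = 20.0,
    exclude_other_rois: bool = True,
) -> list[np.ndarray]:
    """Annulus masks: dilation of each ROI by ``ring_width_um`` minus the
    ROI and (optionally) every other ROI mask."""
    radius_px = max(1, round(ring_width_um / pixel_size_um))
    selem = disk(radius_px)
    all_mask = np.logical_or.reduce([r.mask for r in rois]) if len(rois) else None
    rings = []
    for roi in rois:
        ring = ndimage.binary_dilation(roi.mask, structure=selem) & ~roi.mask
        if exclude_other_rois and all_mask is not None:
            ring &= ~(all_mask & ~roi.mask)
        if not ring.any():
            raise EmptyNeuropilRingError(f"ROI {roi.label}: empty neuropil ring")
        rings.append(ring)
    return rings


def extract_traces(
    movie: Movie | DffMovie,
    rois: RoiSet,
    ring_width_um: float = 20.0,
    exclude_other_rois: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean over each ROI mask (raw) and its neuropil ring.

    Works on either the dF/F movie (default pipeline choice) or the raw
    fluorescence movie.  Returns ``(raw, neuropil)``, each (n_rois, T).
    """
    data = movie.data
    rings = neuropil_ring_masks(
        rois, movie.pixel_size_um, ring_width_um, exclude_other_rois
    )
    n, t = len(rois), data.shape[0]
    raw = np.empty((n, t))
    neuropil = np.empty((n, t))
    flat = data.reshape(t, -1)
    for i, (roi, ring) in enumerate(zip(rois, rings)):
        raw[i] = flat[:, roi.mask.ravel()].mean(axis=1)
        neuropil[i] = flat[:, ring.ravel()].mean(axis=1)
    return raw, neuropil


def neuropil_correct(
    raw: np.ndarray, neuropil: np.ndarray, r: float = 0.7
) -> np.ndarray:
    """``corrected = raw - r * neuropil`` (r = 0.7 by default)."""
    raw = np.asarray(raw, dtype=float)
    neuropil = np.asarray(neuropil, dtype=float)
    if raw.shape != neuropil.shape:
        raise InconsistentLengthError("raw and neuropil shapes differ")
    return raw - r * neuropil


# Neuropil scale presets per imaging system; a single published value is
# adopted for all entries pending system-specific calibration.
NEUROPIL_R_PRESETS: dict[str, float] = {
    "default": 0.7,
    "one_photon_grin": 0.7,
    "miniscope_v3": 0.7,
    "miniscope_v4": 0.7,
}


def detrend(
    trace: np.ndarray,
    frame_rate_hz: float,
    method: Literal["percentile", "linear"] = "percentile",
    window_s: float = 60.0,
    percentile: float = 8.0,
) -> np.ndarray:
    """Remove slow bleaching trends from a 1-D trace.

    Default subtracts a running ``percentile``-baseline (window
    ``window_s`` seconds) and adds back the global median so the output
    keeps the trace's overall level; the alternative subtracts the
    least-squares line.
    """
    trace = np.asarray(trace, dtype=float)
    if method == "linear":
        t = np.arange(trace.size)
        slope, intercept = np.polyfit(t, trace, 1)
        return trace - (slope * t + intercept) + float(np.median(trace))
    window = int(round(window_s * frame_rate_hz))
    if window >= trace.size:
        raise ValueError("window_s must be shorter than the series duration")
    if window < 3:
        raise ValueError("window too small (< 3 samples)")
    # robust opening: a low-percentile pass rejects transients but lags a
    # monotone trend by ~half a window; the complementary high-percentile
    # pass undoes that positional bias (exact for monotone baselines)
    low = ndimage.percentile_filter(trace, percentile, size=window, mode="reflect")
    baseline = ndimage.percentile_filter(low, 100.0 - percentile, size=window, mode="reflect")
    baseline = ndimage.gaussian_filter1d(baseline, sigma=max(1.0, window / 8.0))
    return trace - baseline + float(np.median(trace))


def ar2_impulse_response(g1: float, g2: float, length: int) -> np.ndarray:
    """Kernel h with h[0]=1, h[1]=g1, h[k]=g1 h[k-1] + g2 h[k-2]."""
    h = np.zeros(length)
    if length > 0:
        h[0] = 1.0
    if length > 1:
        h[1] = g1
    for k in range(2, length):
        h[k] = g1 * h[k - 1] + g2 * h[k - 2]
    return h


def ar2_filter(spikes: np.ndarray, g1: float, g2: float) -> np.ndarray:
    """Apply the AR(2) dynamics to a spike train (zero initial conditions)."""
    spikes = np.asarray(spikes, dtype=float)
    # c_t - g1 c_{t-1} - g2 c_{t-2} = s_t  <=>  IIR filter 1/(1 - g1 z^-1 - g2 z^-2)
    return signal.lfilter([1.0], [1.0, -g1, -g2], spikes)


def estimate_noise_sigma(trace: np.ndarray, band: tuple[float, float] = (0.25, 0.5)) -> float:
    """White-noise SD from the high-frequency PSD plateau.

    Calcium dynamics are slow, so the one-sided Welch PSD above a quarter
    of the sampling rate is dominated by the measurement noise floor;
    for white noise of variance ``sigma^2`` that floor is ``2 sigma^2``
    (unit sampling rate).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg = min(256, trace.size)
    freqs, pxx = signal.welch(trace - trace.mean(), fs=1.0, nperseg=nperseg)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        sel = freqs >= freqs.max() / 2
    return float(np.sqrt(np.mean(pxx[sel]) / 2.0))


def _project_stable(g1: float, g2: float, max_modulus: float = 0.99) -> tuple[float, float]:
    disc = g1 * g1 + 4.0 * g2
    sq = np.sqrt(complex(disc))
    p1, p2 = (g1 + sq) / 2.0, (g1 - sq) / 2.0

    def clip(p: complex) -> complex:
        m = abs(p)
        return p if m <= max_modulus else p * (max_modulus / m)

    p1, p2 = clip(p1), clip(p2)
    return float((p1 + p2).real), float(-(p1 * p2).real)


def default_ar2(
    frame_rate_hz: float,
    rise_tau_s: float = 0.08,
    decay_tau_s: float = 0.6,
    noise_sigma: float = 0.0,
) -> Ar2Params:
    """AR(2) coefficients from indicator rise/decay time constants.

    Defaults approximate a fast genetically encoded calcium indicator
    (GCaMP6f-like kinetics).  Used as a fallback when a trace is too
    short to fit its own kinetics.
    """
    d = float(np.exp(-1.0 / (decay_tau_s * frame_rate_hz)))
    r = float(np.exp(-1.0 / (rise_tau_s * frame_rate_hz)))
    return Ar2Params(g1=d + r, g2=-d * r, noise_sigma=noise_sigma)


def fit_ar2(
    trace: np.ndarray,
    frame_rate_hz: float = 1.0,
    max_lag: int = 8,
    lam: float | None = None,
) -> Ar2Params:
    """Estimate AR(2) coefficients and noise SD from a raw trace.

    ``g1, g2`` come from least-squares Yule-Walker equations on
    autocovariance lags 1..``max_lag``; the lag-0 autocovariance is
    corrected by the noise variance (estimated first from the PSD
    plateau) wherever it enters as a regressor.  Unstable estimates are
    projected back inside the unit circle.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 200:
        raise ValueError("need at least 200 samples to fit AR(2) kinetics")
    sigma = estimate_noise_sigma(trace)
    x = trace - trace.mean()
    T = x.size
    acov = np.array(
        [np.dot(x[: T - k], x[k:]) / T for k in range(max_lag + 1)]
    )
    lam0 = acov[0] - sigma**2
    rows, rhs = [], []
    # k = 1: lambda(1) = g1 * (lambda(0) - sigma^2) + g2 * lambda(1)
    rows.append([lam0, acov[1]])
    rhs.append(acov[1])
    # k = 2: lambda(2) = g1 * lambda(1) + g2 * (lambda(0) - sigma^2)
    rows.append([acov[1], lam0])
    rhs.append(acov[2])
    for k in range(3, max_lag + 1):
        rows.append([acov[k - 1], acov[k - 2]])
        rhs.append(acov[k])
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    g1, g2 = _project_stable(float(sol[0]), float(sol[1]))
    if lam is None:
        lam = 0.0
    return Ar2Params(g1=g1, g2=g2, noise_sigma=sigma, lam=lam)


def deconvolve_oasis_ar2(
    detrended: np.ndarray,
    params: Ar2Params,
    lam: float | None = None,
    s_min: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse non-negative deconvolution with AR(2) dynamics (OASIS).

    Solves ``min_s 0.5 ||y - h * s||^2 + lam * sum(s)`` subject to
    ``s >= 0`` (or ``s in {0} U [s_min, inf)`` when ``s_min`` is used)
    with the pool-adjacent-violators style active-set method generalized
    to second-order dynamics: within a pool no spike occurs and the
    fitted calcium follows the homogeneous AR(2) solution; pools are
    merged backwards whenever the spike implied at a pool boundary drops
    below the admissible minimum.

    Returns ``(denoised, spikes)`` where ``denoised`` is exactly the
    AR(2) filtering of ``spikes``.
    """
    y = np.asarray(detrended, dtype=float)
    T = y.size
    g1, g2 = params.g1, params.g2
    if lam is None:
        lam = params.lam
    if s_min is None:
        s_min = params.s_min
    if T == 0:
        return np.zeros(0), np.zeros(0)
    if T < 3:
        s = np.maximum(y, 0.0)
        return ar2_filter(s, g1, g2), s

    # absorb the L1 penalty into the data (lam * sum(s) = lam * mu . c)
    mu = np.full(T, 1.0 - g1 - g2)
    mu[-2] = 1.0 - g1
    mu[-1] = 1.0
    yp = y - lam * mu

    g11 = ar2_impulse_response(g1, g2, T)  # h[k]
    g12 = np.empty(T)
    g12[0] = 0.0
    g12[1:] = g2 * g11[:-1]
    g11g11 = np.cumsum(g11 * g11)
    g11g12 = np.cumsum(g11 * g12)

    def fit_v(f: int, l: int, u: float) -> float:
        num = float(np.dot(g11[:l], yp[f : f + l])) - u * g11g12[l - 1]
        return num / g11g11[l - 1]

    c = np.zeros(T)
    pools: list[list[int]] = []  # [f, l]
    for t in range(T):
        pools.append([t, 1])
        while True:
            f, l = pools[-1]
            u = c[f - 1] if f > 0 else 0.0
            v = fit_v(f, l, u)
            if len(pools) == 1:
                v = max(v, 0.0)
                c[f : f + l] = v * g11[:l] + u * g12[:l]
                break
            cm1 = c[f - 1]
            cm2 = c[f - 2] if f >= 2 else 0.0
            if v - g1 * cm1 - g2 * cm2 >= s_min - 1e-12:
                c[f : f + l] = v * g11[:l] + u * g12[:l]
                break
            fp, lp = pools[-2]
            pools[-2] = [fp, lp + l]
            pools.pop()

    # spikes at pool starts only; inside pools the dynamics are homogeneous
    s = np.zeros(T)
    for f, l in pools:
        cm1 = c[f - 1] if f >= 1 else 0.0
        cm2 = c[f - 2] if f >= 2 else 0.0
        s[f] = c[f] - g1 * cm1 - g2 * cm2
    s[s < max(s_min, 1e-9 * max(1.0, np.abs(c).max()))] = 0.0
    denoised = ar2_filter(s, g1, g2)
    return denoised, s


def detect_events(
    spikes: np.ndarray,
    frame_rate_hz: float,
    k_sigma: float = 3.0,
    min_separation_s: float = 0.5,
) -> np.ndarray:
    """Discrete event times from the deconvolved activity.

    Threshold = ``k_sigma`` times a MAD-based sigma of the nonzero spike
    values; candidate frames above threshold closer together than
    ``min_separation_s`` are collapsed to the larger one.  Returns sorted
    frame indices.
    """
    spikes = np.asarray(spikes, dtype=float)
    if np.any(spikes < 0):
        raise ValueError("spikes must be non-negative")
    nz = spikes[spikes > 0]
    if nz.size == 0:
        return np.zeros(0, dtype=int)
    sigma = float(np.median(np.abs(nz - np.median(nz))) / 0.6745)
    thresh = k_sigma * sigma
    candidates = np.nonzero(spikes > thresh)[0]
    if candidates.size == 0:
        return np.zeros(0, dtype=int)
    min_gap = max(1, int(round(min_separation_s * frame_rate_hz)))
    order = candidates[np.argsort(spikes[candidates])[::-1]]  # largest first
    accepted: list[int] = []
    for idx in order:
        if all(abs(idx - a) >= min_gap for a in accepted):
            accepted.append(int(idx))
    return np.array(sorted(accepted), dtype=int)


def process_traces(
    movie: Movie | DffMovie,
    rois: RoiSet,
    neuropil_r: float = 0.7,
    ring_width_um: float = 20.0,
    detrend_method: Literal["percentile", "linear"] = "percentile",
    detrend_window_s: float = 60.0,
    lam_sigma_factor: float = 1.0,
    s_min_sigma_factor: float = 2.0,
    k_sigma: float = 3.0,
    min_separation_s: float = 0.5,
) -> TraceBundle:
    """Run the full per-ROI chain and return a populated TraceBundle.

    The L1 sparsity penalty for each ROI is ``lam_sigma_factor`` times
    its estimated noise SD, and spikes smaller than ``s_min_sigma_factor``
    noise SDs are rejected (hard minimum spike size), which keeps
    spike-free noise from being explained by trains of tiny spikes.
    """
    frame_rate = movie.frame_rate_hz
    raw, neuropil = extract_traces(movie, rois, ring_width_um)
    corrected = neuropil_correct(raw, neuropil, neuropil_r)
    n, t = corrected.shape
    window_s = min(detrend_window_s, 0.5 * t / frame_rate)
    detrended = np.stack(
        [
            detrend(corrected[i], frame_rate, method=detrend_method, window_s=window_s)
            for i in range(n)
        ]
    )
    denoised = np.zeros_like(detrended)
    spikes = np.zeros_like(detrended)
    events: list[np.ndarray] = []
    ar2_list: list[Ar2Params] = []
    for i in range(n):
        tr = detrended[i] - np.median(detrended[i])
        if tr.size >= 200:
            params = fit_ar2(tr, frame_rate)
        else:  # too short to fit kinetics; fall back to indicator defaults
            params = default_ar2(frame_rate, noise_sigma=estimate_noise_sigma(tr))
        ar2_list.append(params)
        denoised[i], spikes[i] = deconvolve_oasis_ar2(
            tr,
            params,
            lam=lam_sigma_factor * params.noise_sigma,
            s_min=s_min_sigma_factor * params.noise_sigma,
        )
        events.append(detect_events(spikes[i], frame_rate, k_sigma, min_separation_s))
    return TraceBundle(
        raw=raw,
        neuropil=neuropil,
        corrected=corrected,
        detrended=detrended,
        denoised=denoised,
        spikes=spikes,
        events=events,
        frame_rate_hz=frame_rate,
        ar2=ar2_list,
        metadata={
            "neuropil_r": neuropil_r,
            "ring_width_um": ring_width_um,
            "detrend_method": detrend_method,
            "detrend_window_s": window_s,
            "k_sigma": k_sigma,
            "min_separation_s": min_separation_s,
        },
    )
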