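# Methods

This note documents the models, conventions and numerical choices behind
`calimba`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Conventions

Pixel coordinates are 0-based `(row, col)` with the origin at the
top-left; time indices are 0-based. All computation is in float64
regardless of storage dtype; movie writes default to float32 TIFF.
Frame rate and pixel size are user inputs, not parsed from vendor TIFF
tags (vendor metadata varies across recorders and is often wrong after
re-export).

## Pre-processing

**Dust removal.** Each connected component of the user-supplied mask is
filled, per frame, with the mean of an annulus obtained by dilating the
component with a disc of radius `dust_ring_width_px` (default 8 px) and
subtracting the mask. Edge-touching components use only in-frame ring
pixels. Filling precedes everything else because dust is static in
*sensor* coordinates while the tissue moves: left in place it anchors
the motion estimate to the optics instead of the brain, and it distorts
the flat-field gain estimate.

**Corrupted frames.** Let Ī_t be the mean intensity of frame t and
ΔĪ_t = Ī_t − Ī_{t−1}. The threshold is
`thr = multiplier · median(|ΔĪ| / mad_const)` with defaults 5 and
0.6745; the median absolute deviation divided by 0.6745 is a robust
estimator of the SD of a Gaussian, so thr sits five noise-SDs out — the
amplitude-threshold rule familiar from extracellular spike detection.
Frames with |ΔĪ_t| strictly above thr are flagged (a tie is not
"exceeding") and replaced by the nearest preceding unflagged frame; runs
of flagged frames all copy the frame before the run, and flagged frames
at the start copy the nearest following good frame. The threshold is
computed in a single pass; it is not recomputed after replacement.
Replaced indices are kept on the movie (`replaced_frames`) so
deconvolution can ignore duplicated frames if configured.

**Down-sampling.** Movies wider than 100 px are resized to 40% by
default (anti-aliased bilinear), with `pixel_size_um` rescaled by the
realized width ratio. Head-mounted sensors typically oversample the
optical resolution, so this mainly buys speed. Time is never resampled.

**Flat-field correction.** Each frame is divided by a smooth estimate of
the static illumination gain. The default estimator fits a degree-4 2-D
polynomial to the log of the temporal-mean image and exponentiates the
fit. Two properties motivated this choice over a wide Gaussian blur of
the mean image (which is retained as `method="blur"` and used inside the
alignment-quality protocol): a least-squares fit in log space is a
linear projection, so correcting twice changes nothing (idempotence to
machine precision), and it does not suffer the curvature bias by which a
wide blur underestimates a cosine-shaped vignette near the borders (on
the synthetic vignette the polynomial leaves ~1% residual structure
versus ~7% for the blur at σ = 10% of the frame size). Division by any
static field rescales each pixel's time series by one constant, so
temporal dynamics — and ΔF/F, which is scale-invariant per pixel — are
untouched.

## Motion correction

Only rigid translation is modeled; rotation and non-rigid deformation
are out of scope and a documented limitation. Two estimators:

- **Subpixel phase correlation**: upsampled cross-correlation
  (matrix-multiply DFT refinement) with spectral whitening ("phase"
  normalization). Whitening matters on this data: plain cross-correlation
  of a low-contrast frame against a blurry reference is dominated by the
  brightest blob — often a transient — and produces runaway shifts.
- **Lucas–Kanade**: single-level, translation-only Gauss–Newton descent
  on the SSD, with σ = 1 px Gaussian pre-smoothing for gradient
  stability, max 50 iterations, 0.01 px tolerance. Preferred when the
  field of view has visible local features (blood vessels); on the
  synthetic fixtures it tracks sub-noise jitter better than per-frame
  phase correlation.

Matching can use the full frame or a rectangular seed region (≥ 16×16 px;
a centered 40×40 px default is provided). The reference is static
(frame 0, or the temporal mean — the pipeline default, since the mean is
dominated by stable anatomy rather than whichever cell happens to be
active) or dynamic (each frame against its aligned predecessor, shifts
accumulated; useful when no static landmark exists, exploiting the slow
indicator decay that keeps consecutive frames similar). Frames are
resampled bilinearly at the negated shift with edge-value fill, and
`crop_to_valid` removes ceil(max-shift) margins so every retained pixel
was observed in every frame.

**Alignment quality** follows a fixed protocol: flat-field by the
blurred-mean method, crop to the central 80%, min–max normalize each
frame to [0, 1], then Pearson-correlate every frame with the mean of the
processed series. The per-frame r and its median quantify registration;
constant frames are flagged rather than given an r.

## ΔF/F and projection

`ΔF/F = (F_t − F̄)/F̄` with the full-series mean as baseline — no
percentile baseline is offered at this stage because bleaching is
handled per-trace later. The cell-highlighting projection is per-pixel
max over time multiplied by per-pixel temporal SD, min–max normalized;
the product form (configurable to plain max or SD) suppresses bright
static structure while keeping transient-active pixels. The projection
sorts each pixel's series before reducing, which makes it exactly
invariant to frame order despite floating-point summation.

## Cell detection

The T×P ΔF/F matrix is reduced by PCA to `n_pcs` components (default
3× the expected cell count); ICA then unmixes the concatenation of
variance-normalized spatial and temporal PC loadings weighted by μ and
1−μ (μ = 0.5 default; 1 = purely spatial). Components are sign-oriented
so their spatial filter has positive skew — somata are sparse positive
spatial structures, and orientation by temporal skew proved unreliable
when μ mixes domains. With a fixed seed the decomposition is bitwise
reproducible.

Each filter is standardized over pixels, thresholded at z ≥ 3,
hole-filled, cleaned of specks < 5 px and split into 4-connected
components; each component is a candidate ROI. Refinement applies, in
order: the size window (30–300 px) and roundness cutoff (≥ 0.6, with
roundness = 4πA/P², perimeter from the crack-length estimator, clipped
to 1 — the discrete estimator can exceed 1 for small compact shapes);
merging of pairs whose intersection exceeds 30% of the *smaller* ROI
(denominator configurable to union/IoU; merging is transitive via
union–find and idempotent); exclusion of ROIs whose mean brightness on
the mean image falls strictly below the 5% quantile of the ROI
brightness distribution (an absolute floor is available; when all ROIs
tie, nothing is strictly below the quantile and nothing is removed);
and merging of neighboring ROIs (boundary gap ≤ 2 px) with trace
Pearson r strictly above 0.8. Size/roundness boundaries are inclusive
("outside the window" is removed). Manual ROIs added through the audit
API are exempt from the automatic filters and survive re-runs; manual
additions overlapping existing ROIs leave both (audit outranks merge).
The refinement chain never increases the ROI count.

## Traces and deconvolution

Traces are extracted from the ΔF/F movie by default (raw-F mode
available). The neuropil of an ROI is the annulus obtained by dilating
its mask by `round(20 µm / pixel_size_um)` pixels, minus the mask and
minus every other ROI's mask (the exclusion is configurable).
Correction is `corrected = raw − r·neuropil` with r = 0.7; a preset
table maps imaging-system names to r values (all presets currently
0.7, pending system-specific calibration).

**Detrending** subtracts a running 8th-percentile baseline (60-s window)
computed as a robust opening: the low-percentile pass rejects positive
transients but lags a monotone bleaching trend by about half a window,
and a complementary 92nd-percentile pass undoes that positional bias
exactly for monotone baselines. Reflect boundary handling avoids end
artifacts when the series ends mid-transient. The global median is added
back so the trace level is preserved; a least-squares linear detrend is
the alternative. The method used is recorded in the bundle metadata.

**AR(2) fitting.** Indicator kinetics follow
`c_t = g1 c_{t−1} + g2 c_{t−2} + s_t`; with roots d (decay) and
r (rise) of `z² − g1 z − g2`, stability requires |d|, |r| < 1. The noise
SD comes first, from the high-frequency plateau of the Welch PSD
(f ∈ [0.25, 0.5] of the sampling rate; for white noise the one-sided
density there is 2σ²). This estimator assumes calcium dynamics are slow;
a trace whose *signal* has high-frequency content (e.g. a dense spike
drive) inflates it — with sparse firing the bias is a few percent.
g1, g2 then solve least-squares Yule–Walker equations on autocovariance
lags 1–8, with λ(0) replaced by λ(0) − σ² wherever it appears as a
regressor (measurement noise adds only to lag 0). Unstable estimates are
projected back by clipping root moduli to 0.99; traces shorter than 200
samples fall back to GCaMP6f-like defaults (rise 80 ms, decay 600 ms at
the recording's frame rate).

**OASIS AR(2).** The sparse non-negative deconvolution
`min_s ½‖y − h∗s‖² + λ·Σs, s ≥ 0` (or s ∈ {0} ∪ [s_min, ∞)) is solved by
the pool-adjacent-violators style active-set method generalized to
second-order dynamics: within a pool no spike occurs and the calcium
follows the homogeneous AR(2) solution parametrized by its fitted
initial value; pools merge backwards whenever the spike implied at a
boundary falls below the admissible minimum. The λ term is absorbed into
the data exactly (λ·Σs = λ·μᵀc with μ_t = 1−g1−g2 except at the last two
samples). As in the original formulation, the greedy AR(2) pass is a
very close approximation rather than an exact solver; the test suite
cross-checks it against the exact inverse filter on noiseless input and
against dense non-negative least squares on small noisy problems.
Returned `denoised` is *recomputed* as the AR(2) filtering of the
returned spikes, so the conservation identity holds to machine
precision. Defaults in the high-level chain: λ = 1σ and s_min = 2σ of
the per-trace noise estimate. The hard minimum matters because with
slow kinetics 1−g1−g2 ≈ 0.01, so the L1 term alone barely penalizes the
trains of tiny spikes that would otherwise absorb noise; with s_min = 2σ
a pure-noise trace yields essentially zero spike mass while transient
recovery is unaffected.

**Events** are frames where the deconvolved activity exceeds k·σ_MAD
(k = 3, σ from the MAD of the nonzero spike values); candidates closer
than 0.5 s keep only the larger. This event definition is this package's
convention.

## Behavior

Markers are detected per frame by thresholding in HSV space (hue in
degrees with wrap-around support, saturation/value in [0, 1]; presets
for red/green/blue/yellow LED-like colors). Per range, the largest
connected blob of at least `min_blob_px` (default 10) pixels wins —
robustness against reflections and small distractors — and its
value-channel-weighted centroid is the marker position; frames without a
qualifying blob are flagged invalid, never fatal. Heading is the angle
of the marker-1 → marker-2 vector, 0° toward +col, counter-clockwise
positive with image rows flipped to y-up, undefined (flagged) for
coincident points or single-marker mode. The quality report gives the
untracked fraction, gap run-lengths and per-marker counts; gaps up to
0.5 s are linearly interpolated and flagged as such.

Epochs hold ≤ 8 labeled intervals; overlap between different labels is
rejected unless explicitly allowed. Interval membership is half-open
[start, end) so labels partition time without double counting.
Synchronization to the imaging timebase is nearest-neighbor resampling
with a constant user-supplied offset; drift correction is out of scope.

## Joint analyses

Spatial maps bin events by animal position (default 20 px bins, or 2 cm
when px/cm is known); occupancy counts every valid track frame at one
frame period; rate = events/occupancy, masked below 0.2 s occupancy.
Events on untracked frames are excluded and tallied, preserving exact
conservation (every event is in a bin or in the tally). Per-behavior
rates divide in-label event counts by label duration, with unlabeled
time as its own pseudo-label; "normalized activity" is the per-ROI
z-score of rates across labels (this package's definition). Sweeps drop
triggers whose window is truncated, order rows by trigger time, and
report mean and SEM (sample SD/√n).

## Synthetic data

`make_movie` renders: baseline + somata (anisotropic Gaussian discs of
8–20 px diameter, ≥ ~18 px center spacing, AR(2)-filtered Poisson spikes,
0.03 spikes/frame at 10 Hz by default) + neuropil background (coarse
spatiotemporal noise at a ~40 px spatial scale plus a blurred, diluted
copy of the summed cell activity so the 0.7-scaled subtraction is
meaningfully exercised) + static dark vessels, all multiplied by a
radial cosine-bell vignette (gain 0.3 at the corners), plus white
sensor noise (amplitude/SNR); then rigid jitter or drift is applied,
dust discs darken the *sensor* frame (after motion, as on real optics),
and corrupted frames are replaced by near-zero noise. The neuropil
spatial scale is deliberately much coarser than a soma: out-of-focus
background in one-photon imaging has no cell-sized structure, and a
background with soma-scale blobs would be indistinguishable from cells
for any detector. `make_behavior_video` renders one or two colored
marker discs on a textured arena along a smoothed random walk (or sine /
static path), heading from the path tangent, marker 1 behind and marker
2 ahead so the m1→m2 vector equals the heading, with an alternating
walk/rest epoch schedule. `make_trace` is the single-trace version of
the movie's activity model. Every generator is a pure function of
(params, seed).

What the generator does **not** emulate: photon (Poisson) noise
statistics, optics-accurate PSFs, rotation or non-rigid tissue
deformation, indicator saturation and nonlinearity, occlusions or
lighting changes in the arena, and session-to-session drift. Passing
tests therefore demonstrate correctness of the algorithms under the
stated model, not performance on any particular instrument's data.

## Problem sizes

The test suite runs desk-scale problems chosen to exercise every code
path while keeping the whole suite around a minute on one CPU: movies of
60–300 frames at 64–128 px, traces of 2000–5000 samples, 20-seed
parameter-recovery sweeps, 50-shift registration sweeps. The
acceptance script uses a 100 000-sample series for the threshold
calibration, where the estimator's sampling error is well inside the
±0.05 band.

## Known limitations

Rigid translation only; no cross-session cell tracking (appearance and
disappearance of cells across sessions makes identity assignment
ill-posed without extra information); no Bayesian spike inference — the
deconvolved activity is a non-negative driving signal, not a spike
count; behavior/imaging synchronization is a constant offset; AVI/MP4
decoding requires an ffmpeg-capable imageio plugin at runtime (color
TIFF always works).
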