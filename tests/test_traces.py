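"""Trace extraction, neuropil correction, detrending, AR(2) fitting and
OASIS deconvolution."""

import numpy as np
import pytest
from scipy import ndimage, optimize

from calimba.cells import Roi, RoiSet
from calimba.io import Movie
from calimba.synthetic import TraceParams, make_trace
from calimba.traces import (
    Ar2Params,
    UnstableAr2Error,
    ar2_filter,
    ar2_impulse_response,
    deconvolve_oasis_ar2,
    default_ar2,
    detect_events,
    detrend,
    estimate_noise_sigma,
    extract_traces,
    fit_ar2,
    neuropil_correct,
    neuropil_ring_masks,
    process_traces,
)
from conftest import make_movie


def disc(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


class TestExtractTraces:
    def test_constant_movie_gives_constant_series(self):
        movie = make_movie(np.full((5, 60, 60), 3.0), pixel_size=2.0)
        rois = RoiSet([Roi(disc((60, 60), (30, 30), 5), 1)])
        raw, neuropil = extract_traces(movie, rois)
        np.testing.assert_allclose(raw, 3.0)
        np.testing.assert_allclose(neuropil, 3.0)

    def test_ring_radial_extent_matches_pixel_size(self):
        # 20 um at 2 um/px -> ring reaches 10 px beyond the mask
        shape = (80, 80)
        mask = disc(shape, (40, 40), 6)
        rois = RoiSet([Roi(mask, 1)])
        rings = neuropil_ring_masks(rois, pixel_size_um=2.0, ring_width_um=20.0)
        dist = ndimage.distance_transform_edt(~mask)
        assert dist[rings[0]].max() == pytest.approx(10.0, abs=0.8)
        assert not (rings[0] & mask).any()

    def test_other_roi_excluded_from_ring(self):
        shape = (80, 80)
        m1 = disc(shape, (40, 30), 5)
        m2 = disc(shape, (40, 44), 4)  # inside m1's 20-um ring at 2 um/px
        rois = RoiSet([Roi(m1, 1), Roi(m2, 2)])
        rings = neuropil_ring_masks(rois, pixel_size_um=2.0)
        assert not (rings[0] & m2).any()
        # set-difference oracle
        from skimage.morphology import disk as sk_disk

        expected = ndimage.binary_dilation(m1, structure=sk_disk(10)) & ~m1 & ~m2
        np.testing.assert_array_equal(rings[0], expected)


class TestNeuropilCorrect:
    def test_zero_neuropil_identity(self):
        raw = np.random.default_rng(0).normal(size=(2, 50))
        np.testing.assert_array_equal(neuropil_correct(raw, np.zeros_like(raw)), raw)

    def test_identical_series_leaves_30_percent(self):
        x = np.sin(np.linspace(0, 20, 100))[None]
        np.testing.assert_allclose(neuropil_correct(x, x, 0.7), 0.3 * x, rtol=1e-12)

    def test_regression_recovers_r(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=200)
        neuropil = rng.normal(size=200)
        corrected = neuropil_correct(raw, neuropil, 0.7)
        slope = np.linalg.lstsq(
            neuropil[:, None], (raw - corrected)[:, None], rcond=None
        )[0][0, 0]
        assert slope == pytest.approx(0.7, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            neuropil_correct(np.zeros(5), np.zeros(6))


class TestDetrend:
    def test_linear_method_removes_line_exactly(self):
        t = np.arange(600)
        trace = 5.0 - 0.01 * t
        out = detrend(trace, 10.0, method="linear")
        slope = np.polyfit(t, out, 1)[0]
        assert abs(slope) < 1e-9

    def test_percentile_method_removes_bleach(self):
        # exponential bleach on a flat (spike-free) signal
        trace, _, _ = make_trace(
            TraceParams(n_frames=3000, bleach_amplitude=2.0, noise_sigma=0.05,
                        spike_rate_per_frame=0.0),
            seed=2,
        )
        out = detrend(trace, 10.0, window_s=60.0)
        drift = abs(np.median(out[:750]) - np.median(out[-750:]))
        raw_drift = abs(np.median(trace[:750]) - np.median(trace[-750:]))
        assert drift < 0.05 * 2.0
        assert drift < 0.1 * raw_drift

    def test_trend_free_input_nearly_unchanged(self):
        trace, _, _ = make_trace(
            TraceParams(n_frames=2000, bleach_amplitude=0.0, noise_sigma=0.01), seed=3
        )
        out = detrend(trace, 10.0, window_s=60.0)
        rng_span = np.ptp(trace)
        assert np.abs((out - np.median(out)) - (trace - np.median(trace))).max() < 0.02 * rng_span

    def test_window_too_small(self):
        with pytest.raises(ValueError):
            detrend(np.zeros(100), 10.0, window_s=0.1)


class TestFitAr2:
    def test_recovers_known_coefficients(self):
        trace, _, truth = make_trace(TraceParams(n_frames=5000), seed=0)
        fit = fit_ar2(trace, 10.0)
        assert fit.g1 == pytest.approx(truth.g1, abs=0.05)
        assert fit.g2 == pytest.approx(truth.g2, abs=0.05)
        assert fit.noise_sigma == pytest.approx(0.1, rel=0.2)

    def test_median_recovery_over_seeds(self):
        errs = []
        for seed in range(20):
            trace, _, truth = make_trace(TraceParams(n_frames=3000), seed=seed)
            fit = fit_ar2(trace, 10.0)
            errs.append(abs(fit.g1 - truth.g1))
        assert np.median(errs) < 0.05

    def test_noiseless_sigma_near_zero(self):
        # the estimator reads the high-frequency plateau, so a noiseless
        # slow signal must yield ~0
        t = np.arange(4096)
        trace = 3.0 + np.sin(2 * np.pi * t / 500.0)
        assert estimate_noise_sigma(trace) < 1e-3

    def test_unstable_params_rejected(self):
        with pytest.raises(UnstableAr2Error):
            Ar2Params(g1=1.2, g2=0.3)  # root modulus > 1


class TestOasisAr2:
    P = Ar2Params(g1=1.7, g2=-0.712)

    def test_zero_trace(self):
        den, s = deconvolve_oasis_ar2(np.zeros(300), self.P)
        assert not den.any() and not s.any()

    def test_single_impulse_localized(self):
        y = ar2_filter(np.eye(1, 400, 100).ravel() * 2.0, self.P.g1, self.P.g2)
        den, s = deconvolve_oasis_ar2(y, self.P)
        # exact inverse-filter oracle: s_t = y_t - g1 y_{t-1} - g2 y_{t-2}
        oracle = y - self.P.g1 * np.roll(y, 1) - self.P.g2 * np.roll(y, 2)
        oracle[:2] = y[:2] - [0, self.P.g1 * y[0]]
        assert np.argmax(s) == 100 == np.argmax(oracle)
        assert s[100] / s.sum() >= 0.95

    def test_poisson_train_recovered(self):
        rng = np.random.default_rng(3)
        spikes = rng.poisson(0.1, 2000).astype(float)
        y = ar2_filter(spikes, self.P.g1, self.P.g2)
        y += rng.normal(0, 1.0 / 5.0, size=y.size)  # transient SNR 5
        sigma = estimate_noise_sigma(y)
        _, s = deconvolve_oasis_ar2(y, self.P, lam=sigma, s_min=2 * sigma)
        r = np.corrcoef(
            ndimage.gaussian_filter1d(s, 1.0), ndimage.gaussian_filter1d(spikes, 1.0)
        )[0, 1]
        assert r >= 0.8

    def test_conservation_denoised_is_filtered_spikes(self):
        y = ar2_filter(np.eye(1, 300, 50).ravel(), self.P.g1, self.P.g2)
        den, s = deconvolve_oasis_ar2(y, self.P)
        np.testing.assert_allclose(den, ar2_filter(s, self.P.g1, self.P.g2), atol=1e-8)

    def test_penalty_monotonicity(self):
        rng = np.random.default_rng(5)
        spikes = rng.poisson(0.1, 1500).astype(float)
        y = ar2_filter(spikes, self.P.g1, self.P.g2) + rng.normal(0, 0.2, 1500)
        counts_lam = [
            int((deconvolve_oasis_ar2(y, self.P, lam=lam)[1] > 0).sum())
            for lam in [0.0, 5.0, 20.0, 80.0, 200.0]
        ]
        assert counts_lam == sorted(counts_lam, reverse=True)
        counts_smin = [
            int((deconvolve_oasis_ar2(y, self.P, s_min=sm)[1] > 0).sum())
            for sm in [0.0, 0.2, 0.4, 0.8, 1.6]
        ]
        assert counts_smin == sorted(counts_smin, reverse=True)

    def test_matches_dense_nnls_oracle(self):
        # independent oracle: non-negative least squares on the explicit
        # Toeplitz convolution matrix (no sparsity penalty)
        rng = np.random.default_rng(7)
        T = 120
        spikes = np.zeros(T)
        spikes[[20, 55, 90]] = [1.0, 0.7, 1.3]
        y = ar2_filter(spikes, self.P.g1, self.P.g2) + rng.normal(0, 0.02, T)
        h = ar2_impulse_response(self.P.g1, self.P.g2, T)
        K = np.zeros((T, T))
        for j in range(T):
            K[j:, j] = h[: T - j]
        s_nnls, _ = optimize.nnls(K, y)
        _, s = deconvolve_oasis_ar2(y, self.P)
        # both recover the three true spikes at matching times
        big = np.nonzero(s > 0.3)[0]
        big_o = np.nonzero(s_nnls > 0.3)[0]
        np.testing.assert_array_equal(big, [20, 55, 90])
        np.testing.assert_array_equal(big_o, [20, 55, 90])
        np.testing.assert_allclose(s[big], s_nnls[big_o], atol=0.05)

    def test_white_noise_yields_negligible_spikes(self):
        rng = np.random.default_rng(11)
        wn = rng.normal(0, 1.0, 3000)
        fit = fit_ar2(wn, 10.0)
        _, s = deconvolve_oasis_ar2(
            wn - np.median(wn), fit, lam=fit.noise_sigma, s_min=2 * fit.noise_sigma
        )
        assert s.sum() / wn.size < 0.01 * wn.std()

    def test_residual_whitening(self):
        trace, spikes, truth = make_trace(
            TraceParams(n_frames=2000, noise_sigma=0.1, spike_rate_per_frame=0.05),
            seed=4,
        )
        fit = fit_ar2(trace, 10.0)
        den, _ = deconvolve_oasis_ar2(
            trace - np.median(trace), fit, lam=fit.noise_sigma, s_min=2 * fit.noise_sigma
        )

        def lag1(x):
            x = x - x.mean()
            return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))

        resid = (trace - np.median(trace)) - den
        assert lag1(resid) < lag1(trace)


class TestDetectEvents:
    def test_zero_spikes_no_events(self):
        assert detect_events(np.zeros(100), 10.0).size == 0

    def test_three_isolated_bursts(self):
        spikes = np.zeros(300)
        amps = {50: 5.0, 150: 5.5, 250: 6.0}
        for t, amp in amps.items():
            spikes[t] = amp
        # brute-force oracle for the MAD rule on the nonzero values
        nz = np.array(list(amps.values()))
        thr = 3.0 * np.median(np.abs(nz - np.median(nz))) / 0.6745
        assert (nz > thr).all()
        events = detect_events(spikes, 10.0, k_sigma=3.0)
        np.testing.assert_array_equal(events, [50, 150, 250])

    def test_separation_rule_keeps_larger(self):
        spikes = np.zeros(100)
        spikes[40] = 3.0
        spikes[42] = 5.0  # 0.2 s apart at 10 Hz
        events = detect_events(spikes, 10.0, min_separation_s=0.5)
        np.testing.assert_array_equal(events, [42])

    def test_negative_spikes_rejected(self):
        with pytest.raises(ValueError):
            detect_events(np.array([-1.0, 2.0]), 10.0)


class TestEndToEnd:
    def test_event_times_recovered_on_fixture(self):
        # >= 80% of well-separated ground-truth transients found within
        # +/- 2 frames at SNR ~5
        params = TraceParams(
            n_frames=3000, noise_sigma=0.2, spike_rate_per_frame=0.01, amplitude=1.0
        )
        trace, spikes, truth = make_trace(params, seed=6)
        fit = fit_ar2(trace, 10.0)
        _, s = deconvolve_oasis_ar2(
            trace - np.median(trace), fit, lam=fit.noise_sigma, s_min=2 * fit.noise_sigma
        )
        events = detect_events(s, 10.0, k_sigma=1.0, min_separation_s=0.3)
        truth_times = np.nonzero(spikes)[0]
        hits = sum(np.abs(events - t).min() <= 2 for t in truth_times if events.size)
        assert hits / truth_times.size >= 0.8

    def test_process_traces_bundle_consistency(self):
        rng = np.random.default_rng(8)
        T, H, W = 260, 60, 60
        mask = disc((H, W), (30, 30), 5)
        cal = ar2_filter((rng.random(T) < 0.05).astype(float), 1.6, -0.64)
        data = np.full((T, H, W), 40.0) + rng.normal(0, 0.4, (T, H, W))
        data[:, mask] += 12.0 * cal[:, None]
        movie = make_movie(data, pixel_size=2.0)
        bundle = process_traces(movie, RoiSet([Roi(mask, 1)]))
        assert bundle.n_rois == 1 and bundle.n_frames == T
        assert (bundle.spikes >= 0).all()
        for ev in bundle.events:
            assert np.all(np.diff(ev) > 0)
        # denoised trace correlates with the planted calcium signal
        assert np.corrcoef(bundle.denoised[0], cal)[0, 1] > 0.8
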