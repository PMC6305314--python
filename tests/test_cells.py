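"""PCA/ICA detection, ROI metrics, and rule-based refinement."""

import numpy as np
import pytest
from scipy import ndimage

from calimba import synthetic
from calimba.activity import delta_f_over_f
from calimba.cells import (
    IcaResult,
    Roi,
    RoiSet,
    UnknownRoiLabelError,
    audit,
    exclude_low_fluorescence,
    filter_size_shape,
    filters_to_rois,
    load_roiset,
    merge_correlated_neighbors,
    merge_overlapping,
    pca_ica,
    roundness,
    save_roiset,
)
from conftest import make_movie


def disc(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(rr - center[0], cc - center[1]) <= radius


def disc_of_area(shape, center, area):
    """Disc whose pixel count is exactly `area` (grown pixel by pixel)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1]).ravel()
    order = np.argsort(d, kind="stable")[:area]
    mask = np.zeros(shape[0] * shape[1], dtype=bool)
    mask[order] = True
    return mask.reshape(shape)


def iou(a, b):
    return (a & b).sum() / (a | b).sum()


class TestRoundness:
    def test_square_clips_to_one(self):
        # 8x8 square: crack perimeter 28, 4*pi*64/28^2 = 1.026 -> clipped
        mask = np.zeros((12, 12), dtype=bool)
        mask[2:10, 2:10] = True
        assert roundness(mask) == 1.0

    def test_line_is_elongated(self):
        mask = np.zeros((4, 64), dtype=bool)
        mask[1, 2:62] = True
        assert roundness(mask) < 0.6  # removed by the default cutoff

    def test_disc_is_round(self):
        assert roundness(disc((40, 40), (20, 20), 10)) > 0.8


class TestFilterSizeShape:
    def test_area_boundaries_inclusive(self):
        shape = (80, 320)
        rois = RoiSet(
            [
                Roi(disc_of_area(shape, (40, 40 + 80 * i), a), label=i + 1)
                for i, a in enumerate([29, 30, 300, 301])
            ]
        )
        kept = filter_size_shape(rois, 30, 300, 0.0)
        assert sorted(r.area_px for r in kept) == [30, 300]

    def test_roundness_cutoff(self):
        line = np.zeros((8, 80), dtype=bool)
        line[3, 5:65] = True  # 1x60 line, roundness << 0.6
        blob = disc((8, 80), (4, 70), 3.2)
        rois = RoiSet([Roi(line, 1), Roi(blob, 2)])
        kept = filter_size_shape(rois, 1, 10_000, 0.6)
        assert [r.label for r in kept] == [2]

    def test_manual_rois_exempt(self):
        line = np.zeros((8, 80), dtype=bool)
        line[3, 5:65] = True
        rois = RoiSet([Roi(line, 1, source="manual")])
        assert len(filter_size_shape(rois, 30, 300, 0.6)) == 1


class TestMergeOverlapping:
    def _pair_with_shared(self, shared_frac):
        """Two equal-area discs overlapping by the requested fraction of
        the smaller (brute-force search over center separation)."""
        shape = (60, 120)
        a = disc(shape, (30, 40), 10)
        area = a.sum()
        best = None
        for sep in np.arange(0.0, 25.0, 0.25):
            b = disc(shape, (30, 40 + sep), 10)
            frac = (a & b).sum() / min(area, b.sum())
            if best is None or abs(frac - shared_frac) < abs(best[1] - shared_frac):
                best = (b, frac)
        return a, best[0], best[1]

    def test_above_threshold_merges_to_union(self):
        a, b, frac = self._pair_with_shared(0.35)
        assert frac > 0.30
        merged = merge_overlapping(RoiSet([Roi(a, 1), Roi(b, 2)]), 0.30)
        assert len(merged) == 1
        np.testing.assert_array_equal(merged[0].mask, a | b)
        assert merged[0].source == "merged"

    def test_below_threshold_not_merged(self):
        a, b, frac = self._pair_with_shared(0.25)
        assert frac < 0.30
        merged = merge_overlapping(RoiSet([Roi(a, 1), Roi(b, 2)]), 0.30)
        assert len(merged) == 2

    def test_disjoint_unchanged(self):
        a = disc((40, 80), (20, 20), 8)
        b = disc((40, 80), (20, 60), 8)
        merged = merge_overlapping(RoiSet([Roi(a, 1), Roi(b, 2)]))
        assert len(merged) == 2

    def test_transitive_chain(self):
        shape = (40, 120)
        a = disc(shape, (20, 30), 10)
        b = disc(shape, (20, 41), 10)  # 34.7% shared with a and with c
        c = disc(shape, (20, 52), 10)
        rois = RoiSet([Roi(a, 1), Roi(b, 2), Roi(c, 3)])
        fr_ab = (a & b).sum() / min(a.sum(), b.sum())
        fr_ac = (a & c).sum() / min(a.sum(), c.sum())
        assert fr_ab > 0.30 and fr_ac == 0.0
        merged = merge_overlapping(rois, 0.30)
        assert len(merged) == 1
        np.testing.assert_array_equal(merged[0].mask, a | b | c)

    def test_idempotent(self):
        a, b, _ = self._pair_with_shared(0.4)
        once = merge_overlapping(RoiSet([Roi(a, 1), Roi(b, 2)]), 0.30)
        twice = merge_overlapping(once, 0.30)
        assert len(once) == len(twice)
        np.testing.assert_array_equal(once[0].mask, twice[0].mask)


class TestMergeCorrelatedNeighbors:
    def _adjacent_pair(self):
        shape = (30, 60)
        a = disc(shape, (15, 20), 6)
        b = disc(shape, (15, 34), 6)  # boundary gap 2 px
        return RoiSet([Roi(a, 1), Roi(b, 2)])

    def test_identical_traces_merge(self):
        rois = self._adjacent_pair()
        t = np.sin(np.linspace(0, 10, 200))
        merged = merge_correlated_neighbors(rois, np.stack([t, t]), 0.8)
        assert len(merged) == 1

    def test_independent_noise_not_merged(self):
        rois = self._adjacent_pair()
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 400))
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.3
        merged = merge_correlated_neighbors(rois, np.stack([a, b]), 0.8)
        assert len(merged) == 2

    def test_distant_rois_not_merged(self):
        shape = (30, 100)
        rois = RoiSet([Roi(disc(shape, (15, 20), 6), 1), Roi(disc(shape, (15, 80), 6), 2)])
        t = np.sin(np.linspace(0, 10, 200))
        merged = merge_correlated_neighbors(rois, np.stack([t, t]), 0.8)
        assert len(merged) == 2

    def test_trace_count_mismatch(self):
        with pytest.raises(ValueError):
            merge_correlated_neighbors(self._adjacent_pair(), np.zeros((1, 10)), 0.8)


class TestExcludeLowFluorescence:
    def test_equal_brightness_none_removed(self):
        shape = (40, 200)
        movie = make_movie(np.full((3, *shape), 9.0))
        rois = RoiSet([Roi(disc(shape, (20, 20 + 30 * i), 6), i + 1) for i in range(5)])
        assert len(exclude_low_fluorescence(rois, movie, 0.05)) == 5

    def test_dark_outlier_removed(self):
        shape = (60, 60)
        data = np.full((2, *shape), 100.0)
        dark = disc(shape, (50, 50), 4)
        data[:, dark] = 0.0
        rois = [Roi(disc(shape, (10 + 10 * (i // 4), 10 + 12 * (i % 4)), 3), i + 1)
                for i in range(20)]
        rois.append(Roi(dark, 21))
        out = exclude_low_fluorescence(RoiSet(rois), make_movie(data), 0.05)
        assert len(out) == 20 and 21 not in out.labels

    def test_empty_set(self):
        movie = make_movie(np.ones((2, 8, 8)))
        assert len(exclude_low_fluorescence(RoiSet([], frame_shape=(8, 8)), movie)) == 0


class TestAudit:
    def _five(self):
        shape = (40, 200)
        return RoiSet([Roi(disc(shape, (20, 20 + 35 * i), 6), i + 1) for i in range(5)])

    def test_add_and_remove_keeps_count(self):
        rois = self._five()
        new_mask = disc((40, 200), (10, 190), 5)
        out = audit(rois, add_masks=[new_mask], remove_labels=[3])
        assert len(out) == 5
        assert sum(r.source == "manual" for r in out) == 1
        assert 3 not in out.labels

    def test_remove_all(self):
        rois = self._five()
        assert len(audit(rois, remove_labels=rois.labels)) == 0

    def test_overlapping_addition_keeps_both(self):
        rois = self._five()
        overlapping = disc((40, 200), (20, 22), 6)
        out = audit(rois, add_masks=[overlapping])
        assert len(out) == 6

    def test_unknown_label(self):
        with pytest.raises(UnknownRoiLabelError):
            audit(self._five(), remove_labels=[99])


class TestFiltersToRois:
    def _ica_from_filters(self, filters):
        filters = np.asarray(filters, dtype=float)
        return IcaResult(
            spatial_filters=filters,
            temporal_signals=np.zeros((filters.shape[0], 10)),
            n_pcs=filters.shape[0],
            n_ics=filters.shape[0],
            mu=0.5,
        )

    def test_smooth_bump_gives_single_roi(self):
        rr, cc = np.mgrid[0:50, 0:50]
        bump = np.exp(-((rr - 25) ** 2 + (cc - 25) ** 2) / (2 * 4.0**2))
        f = bump / bump.std() * 6  # peak z ~ 6 after standardization
        rois = filters_to_rois(self._ica_from_filters([f]), z_thresh=3)
        assert len(rois) == 1
        assert rois[0].mask[25, 25]

    def test_subthreshold_noise_gives_none(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(-0.5, 0.5, size=(40, 40))  # |z| < 3 for uniform
        rois = filters_to_rois(self._ica_from_filters([f]), z_thresh=3)
        assert len(rois) == 0

    def test_dumbbell_gives_two_rois(self):
        rr, cc = np.mgrid[0:40, 0:80]
        two = (
            np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / (2 * 3.0**2))
            + np.exp(-((rr - 20) ** 2 + (cc - 60) ** 2) / (2 * 3.0**2))
        )
        rois = filters_to_rois(self._ica_from_filters([two * 20]), z_thresh=3)
        assert len(rois) == 2


@pytest.fixture(scope="module")
def five_cell_fixture():
    p = synthetic.MovieParams(
        n_frames=300, height=96, width=96, n_cells=5, snr=10,
        motion_amplitude_px=0, n_corrupted=0, n_dust=0,
        spike_rate_per_frame=0.05, vessels=False,
    )
    movie, truth = synthetic.make_movie(p, seed=11)
    return movie, truth


class TestPcaIca:
    def test_recovers_flashing_cells(self, five_cell_fixture):
        movie, truth = five_cell_fixture
        dff = delta_f_over_f(movie)
        ica = pca_ica(dff, n_pcs=15, n_ics=15, mu=0.5, seed=0)
        best = []
        for mask in truth.cell_masks:
            ious = []
            for f in ica.spatial_filters:
                z = (f - f.mean()) / f.std()
                ious.append(iou(mask, z >= 3) if (z >= 3).any() else 0.0)
            best.append(max(ious))
        assert sum(b >= 0.6 for b in best) >= 4

    def test_seeded_determinism_bitwise(self, five_cell_fixture):
        movie, _ = five_cell_fixture
        dff = delta_f_over_f(movie)
        a = pca_ica(dff, 10, 10, 0.5, seed=3)
        b = pca_ica(dff, 10, 10, 0.5, seed=3)
        np.testing.assert_array_equal(a.spatial_filters, b.spatial_filters)
        np.testing.assert_array_equal(a.temporal_signals, b.temporal_signals)

    def test_identical_traces_disjoint_cells_separated(self):
        # two cells share one temporal trace; the spatial term (mu=0.5)
        # still separates them
        rng = np.random.default_rng(4)
        T, H, W = 120, 48, 96
        trace = np.zeros(T)
        trace[rng.choice(T, 8, replace=False)] = 1.0
        from calimba.traces import ar2_filter

        cal = ar2_filter(trace, 1.2, -0.3)
        m1 = disc((H, W), (24, 24), 6)
        m2 = disc((H, W), (24, 72), 6)
        data = np.full((T, H, W), 50.0)
        data[:, m1] += 20 * cal[:, None]
        data[:, m2] += 20 * cal[:, None]
        data += rng.normal(0, 0.5, size=data.shape)
        dff = delta_f_over_f(make_movie(data))
        ica = pca_ica(dff, 6, 6, mu=0.5, seed=0)
        rois = filters_to_rois(ica, z_thresh=3)
        hits1 = any(iou(r.mask, m1) >= 0.5 for r in rois)
        hits2 = any(iou(r.mask, m2) >= 0.5 for r in rois)
        assert hits1 and hits2

    def test_component_budget_validated(self, five_cell_fixture):
        movie, _ = five_cell_fixture
        dff = delta_f_over_f(movie)
        with pytest.raises(ValueError):
            pca_ica(dff, n_pcs=5, n_ics=10, mu=0.5, seed=0)


class TestRefinePipeline:
    def test_never_increases_roi_count(self, five_cell_fixture):
        from calimba.cells import refine

        movie, _ = five_cell_fixture
        dff = delta_f_over_f(movie)
        ica = pca_ica(dff, 15, 15, 0.5, seed=0)
        raw = filters_to_rois(ica)
        refined = refine(raw, movie)
        assert len(refined) <= len(raw)

    def test_detection_hit_and_false_alarm_rates(self):
        # K=10 fixture at high SNR: hit rate >= 0.8, false alarms <= 0.2
        from calimba.cells import refine

        p = synthetic.MovieParams(
            n_frames=300, n_cells=10, snr=10, motion_amplitude_px=0,
            n_corrupted=0, n_dust=0, spike_rate_per_frame=0.05, vessels=False,
        )
        movie, truth = synthetic.make_movie(p, seed=0)
        dff = delta_f_over_f(movie)
        ica = pca_ica(dff, 30, 30, 0.5, seed=0)
        rois = refine(filters_to_rois(ica), movie)
        hits = sum(
            max((iou(mask, r.mask) for r in rois), default=0.0) >= 0.5
            for mask in truth.cell_masks
        )
        false_alarms = sum(
            max(iou(mask, r.mask) for mask in truth.cell_masks) < 0.3 for r in rois
        )
        assert hits / 10 >= 0.8
        assert false_alarms / max(len(rois), 1) <= 0.2


class TestRoiSetIO:
    def test_save_load_round_trip(self, tmp_path):
        shape = (40, 80)
        rois = RoiSet(
            [Roi(disc(shape, (20, 20), 6), 1), Roi(disc(shape, (20, 60), 5), 2, source="manual")]
        )
        save_roiset(rois, tmp_path / "r.tif", tmp_path / "r.json")
        back = load_roiset(tmp_path / "r.tif", tmp_path / "r.json")
        assert len(back) == 2
        np.testing.assert_array_equal(back[0].mask, rois[0].mask)
        assert back[1].source == "manual"
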