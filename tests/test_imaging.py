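"""Segmentation chain: bandpass, threshold, watershed, measurement."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk

from fructolyze.errors import DegenerateImageError, ParameterError
from fructolyze.imaging import (
    CompetitionTrace,
    ImageFrame,
    SegmentationConfig,
    auto_threshold,
    bandpass_filter,
    compute_competition_trace,
    estimate_confluency,
    measure_objects,
    segment_frame,
    watershed_split,
)
from fructolyze.synthetic import (
    CellFieldSpec,
    CompetitionModel,
    generate_cell_images,
    generate_competition_images,
)


class TestBandpass:
    def test_flat_field_has_no_band_content(self, flat_frame):
        out = bandpass_filter(flat_frame, 2, 16)
        assert np.ptp(out.pixels) == pytest.approx(0.0, abs=1e-9)

    def test_disk_between_cutoffs_retained(self):
        img = np.zeros((256, 256))
        rr, cc = disk((128, 128), 8)
        img[rr, cc] = 100.0
        out = bandpass_filter(ImageFrame(img), 3, 120)
        # centre contrast survives: > 90% of pre-filter contrast
        contrast = out.pixels[128, 128] - np.median(out.pixels)
        assert contrast > 0.9 * 100.0

    def test_high_frequency_checkerboard_suppressed(self):
        period = 2
        tile = np.array([[0.0, 100.0], [100.0, 0.0]])
        img = np.tile(tile, (64, 64))
        out = bandpass_filter(ImageFrame(img), small_cutoff=4, large_cutoff=32)
        assert out.pixels.var() < 0.05 * img.var()

    def test_bad_cutoffs_rejected(self, flat_frame):
        with pytest.raises(ParameterError):
            bandpass_filter(flat_frame, 16, 2)
        with pytest.raises(ParameterError):
            bandpass_filter(flat_frame, 2, 100)


class TestAutoThreshold:
    def test_bimodal_threshold_between_modes(self):
        img = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)]).reshape(20, 50)
        mask, thr = auto_threshold(ImageFrame(img))
        assert 10 < thr < 200
        # the mask separates the two modes exactly
        assert mask.sum() == 500

    def test_noise_free_field_recovered_exactly(self, clean_field):
        mask, _ = auto_threshold(clean_field.phase)
        truth_mask = clean_field.phase.pixels > clean_field.truth.area_px.min() * 0  # placeholder
        # ground truth: cell pixels are exactly those above background level
        truth_mask = clean_field.phase.pixels > 30.0
        np.testing.assert_array_equal(mask, truth_mask)
        assert mask.sum() == clean_field.truth.area_px.sum()

    def test_inverted_image_complementary_mask(self, clean_field):
        img = clean_field.phase.pixels
        normal, _ = auto_threshold(ImageFrame(img))
        flipped, _ = auto_threshold(ImageFrame(img.max() - img), invert=True)
        np.testing.assert_array_equal(normal, flipped)

    def test_constant_image_degenerate(self, flat_frame):
        with pytest.raises(DegenerateImageError):
            auto_threshold(flat_frame)


class TestWatershed:
    @staticmethod
    def _two_disks(sep):
        mask = np.zeros((96, 96), dtype=bool)
        for c in ((48, 30), (48, 30 + sep)):
            rr, cc = disk(c, 10)
            mask[rr, cc] = True
        return mask

    def test_disjoint_disks_match_connected_components(self):
        mask = self._two_disks(sep=40)
        labels = watershed_split(mask)
        cc, n_cc = ndi.label(mask)
        assert labels.max() == n_cc == 2

    def test_touching_disks_split_near_neck(self):
        # overlap < 30% of radius: centres 17 apart for radius 10
        mask = self._two_disks(sep=17)
        cc, n_cc = ndi.label(mask)
        assert n_cc == 1  # genuinely touching
        labels = watershed_split(mask)
        assert labels.max() == 2
        # oracle: the distance transform has exactly two regional maxima
        dist = ndi.distance_transform_edt(mask)
        from skimage.morphology import local_maxima

        peaks, _ = ndi.label(local_maxima(dist) & mask)
        assert peaks.max() == 2
        # each disk centre gets its own label
        assert labels[48, 30] != labels[48, 47]

    def test_single_disk_no_spurious_split(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 12)
        mask[rr, cc] = True
        assert watershed_split(mask).max() == 1

    def test_empty_mask_empty_labeling(self):
        labels = watershed_split(np.zeros((32, 32), dtype=bool))
        assert labels.max() == 0

    def test_labels_refine_components(self, noisy_field):
        res = segment_frame(noisy_field.phase)
        mask = res.label_mask > 0
        _, n_cc = ndi.label(mask, structure=np.ones((3, 3), int))
        assert res.label_mask.max() >= n_cc


class TestMeasureObjects:
    def test_count_and_areas_on_clean_field(self, clean_field):
        res = segment_frame(clean_field.phase, clean_field.red)
        assert res.count == 100
        # per-object areas within 5% of ground truth (matched by position)
        truth = clean_field.truth
        for _, obj in res.objects.iterrows():
            d = np.hypot(truth.row - obj.centroid_row, truth.col - obj.centroid_col)
            t = truth.iloc[int(np.argmin(d))]
            assert abs(obj.area_px - t.area_px) <= 0.05 * t.area_px

    def test_labeled_flags_exact_on_clean_field(self, clean_field):
        res = segment_frame(clean_field.phase, clean_field.red)
        assert res.labeled_count == 50

    def test_all_below_min_area_gives_zero(self, clean_field):
        res = segment_frame(
            clean_field.phase,
            config=SegmentationConfig(min_area=10_000, max_area=20_000),
        )
        assert res.count == 0

    def test_area_conservation_invariant(self, noisy_field):
        res = segment_frame(noisy_field.phase)
        assert res.objects.area_px.sum() == (res.label_mask > 0).sum()

    def test_no_red_channel_still_counts(self, clean_field):
        res = segment_frame(clean_field.phase)
        assert res.count == 100
        assert "is_labeled" not in res.objects.columns

    def test_deterministic(self, noisy_field):
        a = segment_frame(noisy_field.phase, noisy_field.red)
        b = segment_frame(noisy_field.phase, noisy_field.red)
        np.testing.assert_array_equal(a.label_mask, b.label_mask)
        assert a.objects.equals(b.objects)


class TestConfluency:
    def test_empty_field_zero(self):
        spec = CellFieldSpec(n_cells=0, seed=3)
        [fld] = generate_cell_images(spec)
        with pytest.warns(UserWarning):
            assert estimate_confluency(fld.phase) == 0.0

    def test_half_covered_field(self):
        img = np.full((256, 256), 40.0)
        img[:, :128] = 180.0
        img += np.random.default_rng(0).normal(0, 1.0, img.shape)
        est = estimate_confluency(ImageFrame(img))
        assert est == pytest.approx(50.0, abs=2.0)

    def test_mean_over_frames_contract(self):
        frames = []
        singles = []
        for i in range(16):
            spec = CellFieldSpec(n_cells=20 + 5 * i, seed=100 + i)
            [fld] = generate_cell_images(spec)
            frames.append(fld.phase)
            singles.append(estimate_confluency(fld.phase))
        assert estimate_confluency(frames) == pytest.approx(np.mean(singles))

    def test_tracks_true_coverage(self, clean_field):
        true_cover = 100.0 * clean_field.truth.area_px.sum() / clean_field.phase.pixels.size
        assert estimate_confluency(clean_field.phase) == pytest.approx(true_cover, abs=2.0)


class TestCompetitionTrace:
    def test_equal_growth_fraction_near_half(self):
        model = CompetitionModel(f0=0.5, r1=0.0, r2=0.0, times_h=(0.0, 24.0, 48.0),
                                 n0_cells=60)
        spec = CellFieldSpec(field_size=512, radius_mean=6, radius_sd=0.5, seed=9,
                             noise_sd=2.0)
        series, _ = generate_competition_images(model, spec)
        trace = compute_competition_trace(series, SegmentationConfig(min_area=15))
        np.testing.assert_allclose(trace.fraction, 0.5, atol=0.05)

    def test_pure_population_fraction_one(self):
        model = CompetitionModel(f0=1.0, r1=0.0, r2=0.0, times_h=(0.0, 24.0),
                                 n0_cells=40)
        spec = CellFieldSpec(field_size=384, radius_mean=6, seed=2, noise_sd=2.0)
        series, _ = generate_competition_images(model, spec)
        trace = compute_competition_trace(series, SegmentationConfig(min_area=15))
        np.testing.assert_allclose(trace.fraction, 1.0, atol=0.02)

    def test_trace_invariants(self):
        trace = CompetitionTrace(times_h=[0, 24], labeled=[3, 5], total=[10, 10])
        assert np.all((trace.fraction >= 0) & (trace.fraction <= 1))
        with pytest.raises(ParameterError):
            CompetitionTrace(times_h=[0, 24], labeled=[11, 5], total=[10, 10])
        with pytest.raises(ParameterError):
            CompetitionTrace(times_h=[24, 0], labeled=[1, 1], total=[2, 2])

    def test_zero_objects_timepoint_is_nan(self):
        trace = CompetitionTrace(times_h=[0, 24], labeled=[0, 5], total=[0, 10])
        assert np.isnan(trace.fraction[0]) and trace.fraction[1] == 0.5
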