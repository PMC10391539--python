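import numpy as np
import pytest

from thorseg.crop import (CropRegion, CropSpec, centroid, extract_crop, fallback_center,
                          inference_center, paste_crop, paste_esophagus, training_center)
from thorseg.errors import EmptyMaskError, LocalizerError, ValidationError
from thorseg.volume_io import DEFAULT_LABEL_TABLE, LabelVolume

MM1 = (1.0, 1.0)


class TestCentroid:
    def test_two_pixels_average(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 10] = m[10, 12] = True
        assert centroid(m) == (10.0, 11.0)

    def test_single_pixel(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 7] = True
        assert centroid(m) == (5.0, 7.0)

    def test_filled_square(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:7, 3:8] = True
        assert centroid(m) == (4.0, 5.0)

    def test_empty_mask_signals_fallback(self):
        with pytest.raises(EmptyMaskError):
            centroid(np.zeros((4, 4), dtype=bool))


class TestInferenceCenter:
    def test_default_5mm_shifts_at_1mm_pixels(self):
        assert inference_center((200.0, 260.0), MM1, CropSpec()) == (195.0, 255.0)

    def test_coarse_pixels_shrink_the_pixel_offset(self):
        r, c = inference_center((100.0, 100.0), (2.5, 2.5), CropSpec())
        assert (r, c) == (98.0, 98.0)

    def test_zero_shifts_are_identity(self):
        spec = CropSpec(shift_left_mm=0.0, shift_up_mm=0.0)
        assert inference_center((40.0, 50.0), MM1, spec) == (40.0, 50.0)


class TestTrainingCenter:
    def test_zero_jitter_equals_inference_center(self):
        spec = CropSpec(jitter_range_mm=(0.0, 0.0))
        rng = np.random.default_rng(0)
        assert training_center((200.0, 260.0), MM1, spec, rng) == (195.0, 255.0)

    def test_fixed_seed_is_reproducible(self):
        a = training_center((100.0, 100.0), MM1, CropSpec(), np.random.default_rng(3))
        b = training_center((100.0, 100.0), MM1, CropSpec(), np.random.default_rng(3))
        assert a == b

    def test_jitter_magnitudes_bounded_by_4mm(self):
        rng = np.random.default_rng(11)
        base = np.array(inference_center((100.0, 100.0), MM1, CropSpec()))
        mags = [np.linalg.norm(np.array(training_center((100.0, 100.0), MM1, CropSpec(), rng)) - base)
                for _ in range(1000)]
        assert max(mags) <= 4.0 + 1e-9


class TestExtractPaste:
    def test_interior_window_origin_and_content(self):
        img = np.arange(256 * 256, dtype=np.float32).reshape(256, 256)
        crop, region = extract_crop(img, (95.0, 95.0), CropSpec())
        assert region.origin == (63, 63)
        assert region.pad == ((0, 0), (0, 0))
        np.testing.assert_array_equal(crop, img[63:127, 63:127])

    def test_border_window_zero_pads_and_records(self):
        img = np.ones((256, 256), dtype=np.float32)
        crop, region = extract_crop(img, (10.0, 10.0), CropSpec())
        assert crop.shape == (64, 64)
        assert region.pad == ((22, 0), (22, 0))
        assert crop[:22].sum() == 0 and crop[:, :22].sum() == 0
        assert (crop[22:, 22:] == 1).all()

    def test_round_trip_restores_in_bounds_region(self, rng):
        img = rng.normal(0, 1, (100, 100)).astype(np.float32)
        for center in [(50.0, 50.0), (5.0, 95.0)]:
            crop, region = extract_crop(img, center, CropSpec())
            target = img.copy()
            paste_crop(target, crop, region)
            np.testing.assert_array_equal(target, img)


class TestFallback:
    def test_one_mm_leftward_step(self):
        assert fallback_center((100.0, 100.0), MM1, CropSpec()) == (100.0, 99.0)

    def test_chaining_three_steps(self):
        c = (100.0, 100.0)
        for _ in range(3):
            c = fallback_center(c, MM1, CropSpec())
        assert c == (100.0, 97.0)

    def test_zero_step_is_identity(self):
        spec = CropSpec(fallback_step_mm=0.0)
        assert fallback_center((10.0, 20.0), MM1, spec) == (10.0, 20.0)

    def test_no_previous_center_is_a_localizer_error(self):
        with pytest.raises(LocalizerError):
            fallback_center(None, MM1, CropSpec())


class TestPasteEsophagus:
    def _stage1(self):
        labels = np.zeros((1, 8, 8), dtype=np.int16)
        labels[0, 2, 2] = DEFAULT_LABEL_TABLE["trachea"]
        labels[0, 3, 3] = DEFAULT_LABEL_TABLE["esophagus"]  # stage-1 esophagus guess
        labels[0, 5, 5] = DEFAULT_LABEL_TABLE["heart"]
        return LabelVolume(labels, spacing=(5.0, 1.0, 1.0))

    def _region(self):
        return CropRegion(slice_index=0, origin=(0, 0), size=8)

    def test_all_background_crop_clears_esophagus(self):
        out = paste_esophagus(self._stage1(), [(np.zeros((8, 8), bool), self._region())])
        assert not (out.labels == DEFAULT_LABEL_TABLE["esophagus"]).any()

    def test_stage2_foreground_never_overwrites_other_organs(self):
        crop = np.ones((8, 8), dtype=bool)
        out = paste_esophagus(self._stage1(), [(crop, self._region())])
        assert out.labels[0, 2, 2] == DEFAULT_LABEL_TABLE["trachea"]
        assert out.labels[0, 5, 5] == DEFAULT_LABEL_TABLE["heart"]
        assert out.labels[0, 0, 0] == DEFAULT_LABEL_TABLE["esophagus"]  # background claimed
        assert out.labels[0, 3, 3] == DEFAULT_LABEL_TABLE["esophagus"]  # old guess rewritten

    def test_stage1_esophagus_outside_crops_is_removed(self):
        out = paste_esophagus(self._stage1(), [])
        assert not (out.labels == DEFAULT_LABEL_TABLE["esophagus"]).any()

    def test_non_esophagus_labels_bitwise_unchanged(self, rng):
        labels = rng.integers(0, 6, (2, 16, 16)).astype(np.int16)  # codes 0..5
        lv = LabelVolume(labels, spacing=(5.0, 1.0, 1.0))
        crop = rng.random((8, 8)) < 0.5
        region = CropRegion(slice_index=1, origin=(4, 4), size=8)
        out = paste_esophagus(lv, [(crop, region)])
        eso = DEFAULT_LABEL_TABLE["esophagus"]
        np.testing.assert_array_equal(out.labels == 0, ~((labels != 0) | (out.labels == eso)))
        for code in range(1, 6):
            np.testing.assert_array_equal(out.labels == code, labels == code)

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValidationError):
            paste_esophagus(self._stage1(), [(np.zeros((8, 8), bool),
                                              CropRegion(slice_index=4, origin=(0, 0), size=8))])


def test_crop_spec_invariants_enforced():
    with pytest.raises(ValidationError):
        CropSpec(crop_size=63)
    with pytest.raises(ValidationError):
        CropSpec(shift_left_mm=-1.0)
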