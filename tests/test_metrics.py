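import numpy as np
import pytest

from thorseg.errors import EmptyMaskError, ValidationError
from thorseg.metrics import asd, directed_distances, dsc, evaluate_patient, extract_surface, hd95
from thorseg.volume_io import LabelVolume

from _oracles import (brute_asd, brute_hd95, brute_hd100, brute_surface_points,
                      random_mask_pair)

ISO = (1.0, 1.0, 1.0)


def _cube(shape, lo, hi):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


class TestDSC:
    def test_identical_nonempty_masks_score_one(self):
        m = _cube((4, 8, 8), (1, 2, 2), (3, 6, 6))
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = _cube((2, 8, 8), (0, 0, 0), (1, 4, 4))
        b = _cube((2, 8, 8), (1, 4, 4), (2, 8, 8))
        assert dsc(a, b) == 0.0

    def test_half_overlapping_squares_score_half(self):
        # 8x8 squares in one slice, shifted by 4 columns: overlap 32 of 64+64
        a = np.zeros((1, 8, 12), dtype=bool)
        b = np.zeros_like(a)
        a[0, :, 0:8] = True
        b[0, :, 4:12] = True
        assert dsc(a, b) == 0.5

    def test_both_empty_is_one_by_convention(self):
        z = np.zeros((2, 2, 2), dtype=bool)
        assert dsc(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dsc(np.zeros((1, 2, 2), bool), np.zeros((1, 3, 3), bool))


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        np.testing.assert_array_equal(extract_surface(m), m)

    def test_solid_cube_surface_excludes_centre(self):
        m = _cube((5, 5, 5), (1, 1, 1), (4, 4, 4))
        surf = extract_surface(m)
        assert surf.sum() == 26
        assert not surf[2, 2, 2]

    def test_full_volume_surface_is_the_array_boundary(self):
        m = np.ones((4, 5, 6), dtype=bool)
        surf = extract_surface(m)
        interior = np.zeros_like(m)
        interior[1:-1, 1:-1, 1:-1] = True
        np.testing.assert_array_equal(surf, ~interior)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(EmptyMaskError):
            extract_surface(np.zeros((2, 2, 2), bool))


class TestDirectedDistances:
    def test_identical_surfaces_are_all_zero(self):
        m = _cube((3, 5, 5), (0, 1, 1), (2, 4, 4))
        s = extract_surface(m)
        assert directed_distances(s, s, ISO).max() == 0.0

    def test_in_plane_distance_uses_pixel_spacing(self):
        a = np.zeros((1, 1, 5), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[0, 0, 3] = True
        np.testing.assert_allclose(directed_distances(a, b, ISO), [3.0])

    def test_across_slice_distance_uses_slice_thickness(self):
        a = np.zeros((3, 2, 2), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[1, 0, 0] = True
        np.testing.assert_allclose(directed_distances(a, b, (5.0, 1.0, 1.0)), [5.0])


class TestHD95AndASD:
    def test_identity_gives_zero(self):
        m = _cube((3, 6, 6), (0, 1, 1), (3, 5, 5))
        assert hd95(m, m, ISO) == 0.0
        assert asd(m, m, ISO) == 0.0

    def test_singleton_hd95_equals_exact_distance(self):
        a = np.zeros((1, 1, 9), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[0, 0, 5] = True
        assert hd95(a, b, ISO) == pytest.approx(5.0)
        assert asd(a, b, ISO) == pytest.approx(5.0)

    def test_singleton_asd_symmetric_mean(self):
        a = np.zeros((1, 5, 1), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[0, 3, 0] = True
        assert asd(a, b, ISO) == pytest.approx(3.0)

    def test_displaced_line_endpoint_matches_brute_force(self):
        a = np.zeros((1, 12, 21), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, :] = True
        b[0, 0, :20] = True
        b[0, 10, 20] = True  # one endpoint displaced 10 mm laterally
        assert hd95(a, b, ISO) == pytest.approx(brute_hd95(a, b, ISO), abs=1e-9)
        assert asd(a, b, ISO) == pytest.approx(brute_asd(a, b, ISO), abs=1e-9)

    def test_concentric_squares_match_brute_force(self):
        a = np.zeros((1, 13, 13), dtype=bool)
        b = np.zeros_like(a)
        a[0, 1:12, 1:12] = True  # 11x11
        b[0, 3:10, 3:10] = True  # 7x7
        assert hd95(a, b, ISO) == pytest.approx(brute_hd95(a, b, ISO), abs=1e-9)
        assert asd(a, b, ISO) == pytest.approx(brute_asd(a, b, ISO), abs=1e-9)

    def test_empty_mask_is_an_error_not_zero(self):
        m = _cube((2, 3, 3), (0, 0, 0), (1, 2, 2))
        with pytest.raises(EmptyMaskError):
            hd95(m, np.zeros_like(m), ISO)
        with pytest.raises(EmptyMaskError):
            asd(np.zeros_like(m), m, ISO)


class TestMetricProperties:
    def test_symmetry_and_translation_equivariance(self, rng):
        spacing = (5.0, 1.5, 1.5)
        for _ in range(10):
            a, b = random_mask_pair(rng, max_side=10)
            assert dsc(a, b) == dsc(b, a)
            assert hd95(a, b, spacing) == pytest.approx(hd95(b, a, spacing), abs=1e-9)
            assert asd(a, b, spacing) == pytest.approx(asd(b, a, spacing), abs=1e-9)
            # common shift inside an enlarged grid leaves all metrics unchanged
            pad = ((1, 2), (2, 1), (1, 2))
            ash = np.pad(a, pad)
            bsh = np.pad(b, pad)
            assert dsc(ash, bsh) == pytest.approx(dsc(a, b))
            assert hd95(ash, bsh, spacing) == pytest.approx(hd95(a, b, spacing), abs=1e-9)
            assert asd(ash, bsh, spacing) == pytest.approx(asd(a, b, spacing), abs=1e-9)

    def test_hd95_never_exceeds_exact_hausdorff(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng, max_side=10)
            assert hd95(a, b, ISO) <= brute_hd100(a, b, ISO) + 1e-12

    def test_fast_implementation_matches_brute_force_on_random_masks(self, rng):
        spacing = (5.0, 1.0, 1.0)
        for _ in range(20):
            a, b = random_mask_pair(rng, max_side=12)
            assert hd95(a, b, spacing) == pytest.approx(brute_hd95(a, b, spacing), abs=1e-9)
            assert asd(a, b, spacing) == pytest.approx(brute_asd(a, b, spacing), abs=1e-9)

    def test_surface_matches_enumeration(self, rng):
        for _ in range(5):
            a, _ = random_mask_pair(rng, max_side=8)
            pts = brute_surface_points(a)
            surf = np.zeros_like(a)
            surf[tuple(pts.astype(int).T)] = True
            np.testing.assert_array_equal(extract_surface(a), surf)


class TestEvaluatePatient:
    TABLE = {"trachea": 1, "esophagus": 2}

    def _lv(self, labels, spacing=(5.0, 1.0, 1.0)):
        return LabelVolume(labels.astype(np.int16), spacing=spacing, label_table=self.TABLE)

    def test_identical_volumes_score_perfect(self):
        labels = np.zeros((2, 6, 6), dtype=np.int16)
        labels[0, 1:3, 1:3] = 1
        labels[1, 3:5, 3:5] = 2
        recs = {r.organ: r for r in evaluate_patient(self._lv(labels), self._lv(labels))}
        for r in recs.values():
            assert r.dsc == 1.0 and r.hd95 == 0.0 and r.asd == 0.0

    def test_organ_missing_from_prediction(self):
        gt = np.zeros((1, 4, 4), dtype=np.int16)
        gt[0, 1, 1] = 2
        pred = np.zeros_like(gt)
        recs = {r.organ: r for r in evaluate_patient(self._lv(pred), self._lv(gt))}
        assert recs["esophagus"].dsc == 0.0
        assert np.isnan(recs["esophagus"].hd95) and np.isnan(recs["esophagus"].asd)
        # trachea empty in both: perfect overlap by convention, distances missing
        assert recs["trachea"].dsc == 1.0 and np.isnan(recs["trachea"].hd95)

    def test_spacing_mismatch_rejected(self):
        labels = np.zeros((1, 4, 4), dtype=np.int16)
        with pytest.raises(ValidationError):
            evaluate_patient(self._lv(labels), self._lv(labels, spacing=(1.0, 1.0, 1.0)))
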