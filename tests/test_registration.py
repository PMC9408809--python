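import numpy as np
import pytest
from scipy import ndimage

import myodti as m
from myodti.core_io import quaternion_to_matrix
from myodti.registration import dice, rasterize_myocardium


def _annulus_volume(r, inner=20.0, outer=30.0, blood=150.0, myo=100.0, air=5.0, n_slices=3):
    sl = np.where((r >= inner) & (r <= outer), myo, air)
    sl[r < inner] = blood
    return m.Volume3D(np.stack([sl] * n_slices), (8.0, 2.0, 2.0))


class TestRigidAlign:
    def test_identity_for_same_volume(self, annulus_64):
        vol = _annulus_volume(annulus_64["r"])
        t = m.rigid_align(vol, vol)
        np.testing.assert_allclose(t.rotation, [1, 0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_known_rotation(self, annulus_64):
        ang = np.deg2rad(10.0)
        q = np.array([np.cos(ang / 2), 0, 0, np.sin(ang / 2)])
        moving = _annulus_volume(annulus_64["r"])
        fixed = m.Volume3D(moving.data.copy(), moving.spacing_mm, orientation=q)
        t = m.rigid_align(moving, fixed)
        R = quaternion_to_matrix(t.rotation)
        assert np.arctan2(R[1, 0], R[0, 0]) == pytest.approx(ang, abs=1e-6)

    def test_apply_then_invert_is_identity(self):
        t = m.RigidTransform(
            rotation=np.array([np.cos(0.2), 0, 0, np.sin(0.2)]),
            translation=np.array([3.0, -2.0, 5.0]),
        )
        pts = np.random.default_rng(0).normal(scale=30, size=(100, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_zero_orientation_rejected(self):
        with pytest.raises(ValueError):
            m.RigidTransform(rotation=np.zeros(4), translation=np.zeros(3))


class TestLongitudinalRescale:
    def test_scale_075(self):
        z = np.arange(0.0, 33.0, 8.0)
        out = m.longitudinal_rescale(z, 0.0, 24.0)
        np.testing.assert_allclose(out, [0, 6, 12, 18, 24])

    def test_identity_for_equal_spans(self):
        z = np.array([2.0, 10.0, 18.0])
        np.testing.assert_allclose(m.longitudinal_rescale(z, 2.0, 18.0), z)

    def test_endpoints_map_exactly(self):
        z = np.array([-4.0, 3.0, 9.0, 28.0])
        out = m.longitudinal_rescale(z, 1.0, 19.0)
        assert out[0] == 1.0 and out[-1] == 19.0

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            m.longitudinal_rescale(np.array([4.0]), 0.0, 24.0)


class TestEdgeDetection:
    def test_annulus_radii_recovered(self, annulus_64):
        vol = _annulus_volume(annulus_64["r"])
        c = m.detect_myocardial_edges(vol.data[0], (2.0, 2.0))
        endo_r, epi_r = c.mean_radii_mm()
        assert endo_r == pytest.approx(20.0, abs=2.0)
        assert epi_r == pytest.approx(30.0, abs=2.0)

    def test_blank_slice_raises(self):
        with pytest.raises(ValueError, match="contours"):
            m.detect_myocardial_edges(np.zeros((64, 64)), (2.0, 2.0))

    def test_epi_encloses_endo(self, annulus_64):
        vol = _annulus_volume(annulus_64["r"])
        c = m.detect_myocardial_edges(vol.data[0], (2.0, 2.0))
        assert c.epi_mask.sum() > c.endo_mask.sum()
        assert (c.epi_mask | c.endo_mask).sum() == c.epi_mask.sum()  # nesting

    def test_rasterized_mask_matches_analytic(self, annulus_64):
        vol = _annulus_volume(annulus_64["r"])
        c = m.detect_myocardial_edges(vol.data[0], (2.0, 2.0))
        assert dice(rasterize_myocardium(c, (64, 64), (2.0, 2.0)), annulus_64["mask_20_30"]) > 0.9


class TestWeightedAverageMasks:
    def test_endpoint_weights_return_inputs(self, annulus_64):
        r = annulus_64["r"]
        m1 = (r >= 20) & (r <= 30)
        m2 = (r >= 22) & (r <= 32)
        assert np.array_equal(m.weighted_average_masks(m2, m1, 8.0, 0.0, 0.0), m1)
        assert np.array_equal(m.weighted_average_masks(m2, m1, 8.0, 0.0, 8.0), m2)

    def test_identical_masks_midpoint(self, annulus_64):
        mk = annulus_64["mask_20_30"]
        assert np.array_equal(m.weighted_average_masks(mk, mk, 8.0, 0.0, 4.0), mk)

    def test_midpoint_interpolates_concentric_annuli(self, annulus_64):
        """Midpoint of annuli (20/30) and (22/32) is an annulus near (21/31)."""
        r, theta = annulus_64["r"], annulus_64["theta"]
        m1 = (r >= 20) & (r <= 30)
        m2 = (r >= 22) & (r <= 32)
        avg = m.weighted_average_masks(m2, m1, 8.0, 0.0, 4.0)
        bins = np.digitize(theta[avg], np.linspace(-180, 180, 37))
        inner = np.mean([r[avg][bins == b].min() for b in np.unique(bins)])
        outer = np.mean([r[avg][bins == b].max() for b in np.unique(bins)])
        assert inner == pytest.approx(21.0, abs=2.0)
        assert outer == pytest.approx(31.0, abs=2.0)

    def test_target_outside_bracket_rejected(self, annulus_64):
        mk = annulus_64["mask_20_30"]
        with pytest.raises(ValueError):
            m.weighted_average_masks(mk, mk, 8.0, 0.0, 9.0)


class TestNonrigidRegister:
    def _sector_labels(self, annulus):
        r, theta = annulus["r"], annulus["theta"]
        lab = np.where(annulus["mask_20_30"], 1, 0).astype(np.int16)
        lab[(lab > 0) & (np.abs(theta) <= 45)] = 3
        lab[(lab > 0) & (np.abs(theta) > 45) & (np.abs(theta) <= 80)] = 2
        return lab

    def test_identity_case(self, annulus_64):
        lab = self._sector_labels(annulus_64)
        field, warped, d = m.nonrigid_register(lab, lab > 0, (2.0, 2.0))
        assert field.max_displacement_mm < 0.1 * 2.0
        assert np.array_equal(warped, lab)
        assert d == pytest.approx(1.0)

    def test_recovers_dilation(self, annulus_64):
        lab = self._sector_labels(annulus_64)
        fixed = ndimage.binary_dilation(lab > 0, iterations=2)
        _, warped, d = m.nonrigid_register(lab, fixed, (2.0, 2.0))
        assert d >= 0.95
        assert set(np.unique(warped)) <= {0, 1, 2, 3}

    def test_empty_mask_rejected(self, annulus_64):
        with pytest.raises(ValueError, match="empty"):
            m.nonrigid_register(np.zeros((8, 8), np.int16), np.ones((8, 8), bool), (2.0, 2.0))


class TestInterpolateLabels:
    def _map(self, stacks, z):
        return m.LabelMap(np.asarray(stacks, np.int16), (8.0, 2.0, 2.0), np.asarray(z, float))

    def test_existing_slice_unchanged(self):
        stack = np.random.default_rng(0).integers(0, 4, (3, 6, 6))
        lm = self._map(stack, [0, 8, 16])
        out = m.interpolate_labels_to_slices(lm, np.array([8.0]))
        assert np.array_equal(out.labels[0], stack[1])

    def test_constant_column_preserved(self):
        lm = self._map(np.ones((2, 2, 2)), [0, 8])
        out = m.interpolate_labels_to_slices(lm, np.array([4.0]))
        assert np.all(out.labels == 1)

    def test_tie_goes_to_more_severe(self):
        a = np.full((2, 2), 2, np.int16)  # border
        b = np.full((2, 2), 3, np.int16)  # infarct
        lm = self._map(np.stack([a, b]), [0, 8])
        out = m.interpolate_labels_to_slices(lm, np.array([4.0]))
        assert np.all(out.labels == 3)

    def test_extrapolation_uses_nearest(self):
        lm = self._map(np.stack([np.ones((2, 2)), 3 * np.ones((2, 2))]), [0, 8])
        out = m.interpolate_labels_to_slices(lm, np.array([-5.0, 20.0]))
        assert np.all(out.labels[0] == 1) and np.all(out.labels[1] == 3)


class TestFullChain:
    def test_identity_transform_recovers_diastolic_labels(self):
        cfg = m.PhantomConfig(seed=21, systolic_wall_thickening=0.0, systolic_z_scale=1.0)
        study = m.make_lv_phantom(cfg)
        reg, _ = m.register_labels(study.truth_labels_diastole, study.lge, study.dwi)
        truth = study.truth_labels_systole.labels
        d = m.dice_per_class(reg.labels, truth)
        assert min(d.values()) >= 0.85

    def test_default_phantom_dice_and_rescale_ablation(self, default_phantom):
        """Per-class Dice >= 0.85; skipping the z rescale strictly hurts."""
        study = default_phantom
        reg, diag = m.register_labels(study.truth_labels_diastole, study.lge, study.dwi)
        truth = study.truth_labels_systole.labels
        d = m.dice_per_class(reg.labels, truth)
        assert min(d.values()) >= 0.85
        assert set(np.unique(reg.labels)) <= {0, 1, 2, 3}
        # final map partitions the detected cDTI myocardium
        counts = reg.region_counts()
        assert sum(counts.values()) == int((reg.labels > 0).sum())

        reg2, _ = m.register_labels(
            study.truth_labels_diastole, study.lge, study.dwi,
            m.RegistrationConfig(skip_longitudinal_rescale=True),
        )
        d2 = m.dice_per_class(reg2.labels, truth)
        assert np.mean(list(d2.values())) < np.mean(list(d.values()))
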