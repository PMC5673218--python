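"""Quantification: geometric mean, background weighting, VOIs, overlap, PVC."""
import math

import numpy as np
import pytest
from scipy import ndimage

from lutadose.errors import GeometryError, QuantificationError
from lutadose.phantom import CalibrationStandard, organ_activity
from lutadose.quantify import (
    ROI2D,
    VOI3D,
    auto_background_band,
    background_weighting,
    correct_background,
    geometric_mean,
    hybrid_rescale,
    planar_organ_activity,
    planar_sensitivity,
    project_voi,
    recovery_coefficient,
    remove_overlap_and_substitute,
    sensitivity_from_standard,
    voi_activity,
)


class TestGeometricMean:
    def test_pixelwise_sqrt_product(self):
        a = np.full((4, 4), 100.0)
        p = np.full((4, 4), 400.0)
        assert np.allclose(geometric_mean(a, p), 200.0)

    def test_identity_for_equal_images(self):
        a = np.random.default_rng(0).uniform(0, 50, (6, 5))
        sym = a + a[::-1, :]  # left-right symmetric so the mirror is a no-op
        assert np.allclose(geometric_mean(sym, sym), sym)

    def test_zero_propagates(self):
        a = np.ones((3, 3))
        a[1, 1] = 0.0
        gm = geometric_mean(a, np.ones((3, 3)))
        assert gm[1, 1] == 0.0

    def test_posterior_mirror_realigns_asymmetric_source(self):
        """A source off-centre in x appears mirrored in the posterior camera
        frame; the geometric mean must re-align it to the anterior frame."""
        ant = np.zeros((8, 4))
        ant[2, 1] = 100.0
        post = np.zeros((8, 4))
        post[8 - 1 - 2, 1] = 400.0  # camera-mirrored position
        gm = geometric_mean(ant, post)
        assert gm[2, 1] == pytest.approx(200.0)
        assert gm.sum() == pytest.approx(200.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            geometric_mean(np.ones((3, 3)), np.ones((3, 4)))

    def test_symmetric_and_homogeneous(self):
        # the combination itself (mirroring aside) is symmetric and
        # homogeneous of degree 1
        rng = np.random.default_rng(1)
        a, p = rng.uniform(0, 10, (2, 5, 5))
        assert np.allclose(
            geometric_mean(a, p, mirror_posterior=False),
            geometric_mean(p, a, mirror_posterior=False),
        )
        assert np.allclose(geometric_mean(3 * a, 3 * p), 3 * geometric_mean(a, p))


class TestBackgroundWeighting:
    @pytest.mark.parametrize(
        "d_organ, d_body, wf",
        [(4.5, 25.0, 0.82), (0.0, 20.0, 1.0), (20.0, 20.0, 0.0)],
    )
    def test_thickness_factor(self, d_organ, d_body, wf):
        assert background_weighting(d_organ, d_body) == pytest.approx(wf)

    def test_invalid_extents_rejected(self):
        with pytest.raises(QuantificationError):
            background_weighting(30.0, 25.0)
        with pytest.raises(QuantificationError):
            background_weighting(1.0, 0.0)

    def test_bounds_over_valid_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            d_body = rng.uniform(0.1, 40.0)
            d_organ = rng.uniform(0.0, d_body)
            assert 0.0 <= background_weighting(d_organ, d_body) <= 1.0


class TestCorrectBackground:
    def test_weighted_subtraction(self):
        corrected, floored = correct_background(1000.0, 50, 500.0, 50, 0.8)
        assert corrected == pytest.approx(600.0)
        assert not floored

    def test_zero_weight_is_identity(self):
        corrected, _ = correct_background(1000.0, 50, 999.0, 10, 0.0)
        assert corrected == 1000.0

    def test_floor_is_flagged(self):
        corrected, floored = correct_background(10.0, 50, 1000.0, 10, 1.0)
        assert corrected == 0.0
        assert floored


class TestSensitivity:
    def test_counts_rate_over_activity(self):
        assert planar_sensitivity(19600.0, 100.0, 196.0) == pytest.approx(1.0)

    def test_rate_invariant_under_duration(self):
        assert planar_sensitivity(39200.0, 200.0, 196.0) == pytest.approx(
            planar_sensitivity(19600.0, 100.0, 196.0)
        )

    def test_decay_correction_doubles_after_one_half_life(self):
        std = CalibrationStandard(nominal_activity_mbq=196.0, volume_ml=50.0)
        std.duration_s = 100.0
        std.measurements = {159.528: 19600.0}
        corrected = sensitivity_from_standard(std, 159.528, 159.528)
        naive = planar_sensitivity(19600.0, 100.0, 196.0)
        assert corrected == pytest.approx(2.0 * naive, rel=1e-9)

    def test_zero_counts_rejected(self):
        with pytest.raises(QuantificationError, match="field of view"):
            planar_sensitivity(0.0, 100.0, 196.0)


class TestPlanarOrganActivity:
    def test_recovers_truth_without_physics(self, no_physics_study):
        s = no_physics_study
        t = s.time_points_h[1]
        ant, post = s.planar[t]
        gm = geometric_mean(ant, post)
        o = s.phantom.spec.organ("kidney")
        mask = s.phantom.masks["kidney"].any(axis=1)
        band = auto_background_band(mask)
        a, floored = planar_organ_activity(
            gm,
            ROI2D("kidney", mask, band),
            0.8,
            s.acq.planar_sensitivity_cps_per_mbq,
            s.acq.planar_duration_s,
        )
        truth = organ_activity(o, s.admin, t, s.acq.physical_half_life_h)
        assert a == pytest.approx(truth, rel=0.01)
        assert not floored

    def test_attenuation_biases_isolated_organ_low(self, attenuated_study):
        """Without attenuation correction, a deep isolated organ's conjugate-
        view activity falls below truth (syringe calibrated in air)."""
        s = attenuated_study
        t = s.time_points_h[0]
        gm = geometric_mean(*s.planar[t])
        sens = sensitivity_from_standard(s.calibration, t, s.acq.physical_half_life_h)
        mask = s.phantom.masks["kidney_left"].any(axis=1)  # no projection overlap
        a, _ = planar_organ_activity(
            gm, ROI2D("kidney_left", mask, None), 1.0, sens, s.acq.planar_duration_s
        )
        truth = organ_activity(
            s.phantom.spec.organ("kidney_left"), s.admin, t, s.acq.physical_half_life_h
        )
        assert a < truth

    def test_projection_overlap_biases_organ_high(self, paper_study):
        """The liver column through the right kidney ROI inflates its counts —
        the overestimation mechanism of planar-only dosimetry."""
        s = paper_study
        t = s.time_points_h[0]
        gm = geometric_mean(*s.planar[t])
        sens = sensitivity_from_standard(s.calibration, t, s.acq.physical_half_life_h)
        mask = s.phantom.masks["kidney_right"].any(axis=1)
        a, _ = planar_organ_activity(
            gm, ROI2D("kidney_right", mask, None), 1.0, sens, s.acq.planar_duration_s
        )
        truth = organ_activity(
            s.phantom.spec.organ("kidney_right"), s.admin, t, s.acq.physical_half_life_h
        )
        assert a > truth

    def test_zero_activity_organ_reads_near_zero(self):
        gm = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:4, 2:4] = True
        a, _ = planar_organ_activity(gm, ROI2D("x", mask, None), 1.0, 5.0, 100.0)
        assert a == pytest.approx(0.0, abs=1e-12)


class TestVOIActivity:
    def test_exact_sum_without_blur(self, no_physics_study):
        s = no_physics_study
        t = s.time_points_h[0]
        for o in s.phantom.spec.organs:
            voi = VOI3D(o.name, s.phantom.masks[o.name])
            truth = organ_activity(o, s.admin, t, s.acq.physical_half_life_h)
            assert voi_activity(s.spect[t], voi) == pytest.approx(truth, rel=1e-9)

    def test_calibration_factor_scales(self, no_physics_study):
        s = no_physics_study
        t = s.time_points_h[0]
        voi = VOI3D("kidney", s.phantom.masks["kidney"])
        assert voi_activity(s.spect[t], voi, 2.0) == pytest.approx(
            2.0 * voi_activity(s.spect[t], voi), rel=1e-12
        )

    def test_blur_loss_matches_recovery_model(self):
        """VOI under-recovery of a blurred sphere equals the model RC."""
        from lutadose.phantom import Shape, build_phantom, render_activity_volume
        from lutadose.quantify import RecoveryModel
        from test_phantom import make_spec, organ

        spec = make_spec(
            [organ("s", Shape("sphere", (40.0, 40.0, 40.0), (12.0,)))],
            voxel=2.0,
        )
        ph = build_phantom(spec)
        fwhm = 10.0
        vol = render_activity_volume(ph, {"s": 100.0}, psf_fwhm_mm=fwhm)
        measured = voi_activity(vol, VOI3D("s", ph.masks["s"]))
        rc = RecoveryModel(fwhm).coefficient(ph.organ_volume_ml("s"))
        assert measured / 100.0 == pytest.approx(rc, rel=0.02)

    def test_empty_voi_rejected(self):
        with pytest.raises(QuantificationError):
            VOI3D("x", np.zeros((4, 4, 4), dtype=bool))


class TestProjectVOI:
    def test_full_and_single(self):
        full = VOI3D("a", np.ones((4, 5, 6), dtype=bool))
        assert project_voi(full).mask.all()
        single = np.zeros((4, 5, 6), dtype=bool)
        single[1, 2, 3] = True
        roi = project_voi(VOI3D("b", single))
        assert roi.mask.sum() == 1
        assert roi.mask[1, 3]

    def test_projection_overlap_preserves_3d_disjointness(self):
        a = np.zeros((6, 8, 6), dtype=bool)
        b = np.zeros((6, 8, 6), dtype=bool)
        a[2:4, 0:2, 2:4] = True
        b[2:4, 5:7, 2:4] = True  # same columns, different depth
        assert not np.any(a & b)
        assert np.any(project_voi(VOI3D("a", a)).mask & project_voi(VOI3D("b", b)).mask)


class TestOverlapSubstitution:
    def _boxes(self, overlap_cols: int):
        """organ: 10x10 column footprint; blocker shifted to cover
        ``overlap_cols`` of its 10 x-columns at a different depth."""
        organ = np.zeros((30, 12, 20), dtype=bool)
        organ[5:15, 2:6, 5:15] = True
        blocker = np.zeros_like(organ)
        if overlap_cols:
            blocker[15 - overlap_cols : 25 - overlap_cols, 8:11, 5:15] = True
        else:
            blocker[20:28, 8:11, 5:15] = True
        return VOI3D("organ", organ), VOI3D("blocker", blocker)

    def test_no_overlap_gives_unit_factors(self):
        v1, v2 = self._boxes(0)
        corr = remove_overlap_and_substitute([v1, v2])
        assert corr["organ"].substitution_factor == 1.0
        assert corr["blocker"].substitution_factor == 1.0

    def test_thirty_percent_overlap_exact_recovery(self):
        """Uniform organ, 30% of voxels behind the removed pixels: the
        V_total/V_residual factor makes the substitution exact."""
        v1, v2 = self._boxes(3)
        corr = remove_overlap_and_substitute([v1, v2])
        assert corr["organ"].substitution_factor == pytest.approx(1.0 / 0.7, rel=1e-12)
        # uniform unit concentration: measured-on-residual x factor == truth
        conc = 2.5
        vol = np.where(v1.mask, conc, 0.0)
        residual_cols = np.expand_dims(corr["organ"].residual_mask, 1)
        measured = vol[v1.mask & residual_cols].sum()
        truth = vol[v1.mask].sum()
        assert measured * corr["organ"].substitution_factor == pytest.approx(
            truth, rel=1e-12
        )

    def test_hot_spot_in_removed_part_underestimates(self):
        """Inhomogeneous uptake breaks the uniformity assumption: a hot region
        behind the removed pixels makes the substituted estimate low."""
        v1, v2 = self._boxes(3)
        corr = remove_overlap_and_substitute([v1, v2])
        vol = np.where(v1.mask, 1.0, 0.0)
        removed_cols = ~corr["organ"].residual_mask
        hot = v1.mask & np.expand_dims(removed_cols, 1)
        vol[hot] = 5.0  # hot spot entirely in the removed region
        residual_cols = np.expand_dims(corr["organ"].residual_mask, 1)
        measured = vol[v1.mask & residual_cols].sum()
        truth = vol[v1.mask].sum()
        assert measured * corr["organ"].substitution_factor < truth

    def test_factors_at_least_one(self):
        v1, v2 = self._boxes(5)
        for c in remove_overlap_and_substitute([v1, v2]).values():
            assert c.substitution_factor >= 1.0

    def test_fully_occluded_organ_named(self):
        organ = np.zeros((10, 8, 10), dtype=bool)
        organ[2:5, 1:3, 2:5] = True
        blocker = np.zeros_like(organ)
        blocker[1:6, 5:7, 1:6] = True
        with pytest.raises(QuantificationError, match="organ"):
            remove_overlap_and_substitute(
                [VOI3D("organ", organ), VOI3D("blocker", blocker)]
            )

    def test_host_pair_keeps_enclosed_lesion(self):
        host = np.zeros((12, 8, 12), dtype=bool)
        host[2:10, 2:6, 2:10] = True
        lesion = np.zeros_like(host)
        lesion[5:7, 3:5, 5:7] = True
        host &= ~lesion
        corr = remove_overlap_and_substitute(
            [VOI3D("host", host), VOI3D("lesion", lesion)],
            host_pairs={("lesion", "host")},
        )
        assert corr["lesion"].residual_mask.any()
        assert not np.any(corr["host"].residual_mask & corr["lesion"].residual_mask)


class TestHybridRescale:
    def test_rescale_to_spect_value(self):
        out = hybrid_rescale([4.0, 24.0, 48.0], [10.0, 5.0, 2.5], 10.0, 24.0)
        assert np.allclose(out, [20.0, 10.0, 5.0])

    def test_identity_when_spect_equals_planar(self):
        out = hybrid_rescale([4.0, 24.0], [8.0, 4.0], 4.0, 24.0)
        assert np.allclose(out, [8.0, 4.0])

    def test_rate_invariant_under_rescaling(self):
        from lutadose.kinetics import TimeActivityCurve, fit_monoexp

        t = np.array([4.0, 24.0, 48.0, 72.0, 168.0])
        a = 90.0 * np.exp(-0.02 * t)
        scaled = hybrid_rescale(t, a, 37.5, 24.0)
        f1 = fit_monoexp(TimeActivityCurve("x", t, a))
        f2 = fit_monoexp(TimeActivityCurve("x", t, scaled))
        assert f1.lambda_eff_per_h == pytest.approx(f2.lambda_eff_per_h, rel=1e-12)

    def test_requires_positive_reference(self):
        with pytest.raises(QuantificationError):
            hybrid_rescale([4.0, 24.0], [1.0, 0.0], 5.0, 24.0)
        with pytest.raises(QuantificationError):
            hybrid_rescale([4.0, 24.0], [1.0, 0.5], 5.0, 12.0)


class TestRecoveryCoefficient:
    def test_no_blur_full_recovery(self):
        assert recovery_coefficient(0.0, 5.0) == 1.0

    def test_monotone_to_one_with_volume(self):
        vols = [0.5, 2.0, 10.0, 50.0, 500.0, 5000.0]
        rcs = [recovery_coefficient(10.0, v) for v in vols]
        assert all(b > a for a, b in zip(rcs, rcs[1:]))
        assert all(0 < rc <= 1 for rc in rcs)
        # the boundary deficit shrinks like sigma/R, so the limit needs a
        # sphere radius far beyond the PSF width
        assert recovery_coefficient(10.0, 1e7) > 0.99

    def test_matches_brute_force_convolution(self):
        """Sphere with diameter == FWHM, checked against a direct 3D
        convolution on a fine grid."""
        fwhm = 10.0
        radius = fwhm / 2.0
        volume_ml = 4.0 / 3.0 * math.pi * radius**3 / 1000.0
        voxel = 0.5
        n = int(np.ceil((radius + 4 * fwhm) / voxel)) * 2 + 1
        ax = (np.arange(n) - (n - 1) / 2) * voxel
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        sph = X**2 + Y**2 + Z**2 <= radius**2
        sigma = fwhm / (2 * math.sqrt(2 * math.log(2))) / voxel
        blurred = ndimage.gaussian_filter(sph.astype(float), sigma, mode="constant")
        brute = blurred[sph].sum() / sph.sum()
        assert recovery_coefficient(fwhm, volume_ml) == pytest.approx(brute, rel=0.02)

    def test_invalid_volume_rejected(self):
        with pytest.raises(QuantificationError):
            recovery_coefficient(8.0, 0.0)


class TestBackgroundBand:
    def test_band_avoids_exclusions(self):
        roi = np.zeros((20, 20), dtype=bool)
        roi[5:9, 5:9] = True
        other = np.zeros_like(roi)
        other[9:13, 4:10] = True
        band = auto_background_band(roi, exclude=other)
        assert band.any()
        assert not np.any(band & roi)
        assert not np.any(band & other)

    def test_error_when_no_room(self):
        roi = np.ones((6, 6), dtype=bool)
        with pytest.raises(QuantificationError):
            auto_background_band(roi)
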