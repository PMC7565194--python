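"""Affine estimation, warping, cropping and landmark alignment."""

import numpy as np
import pytest

from cycifpipe.errors import CroppingError, ParameterError, RegistrationError
from cycifpipe.registration import (
    AffineTransform,
    align_brightfield,
    align_experiment,
    crop_common_region,
    estimate_affine,
    warp,
    warp_array,
)
from cycifpipe.synthetic import generate_ground_truth, render_cycles

from conftest import small_sim_config


def center_of(img):
    return ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)


def landmark_error(est, true_t, centers):
    """Mean displacement of true cell centers mapped through the estimated
    instead of the true transform."""
    moving = true_t.inverse().apply(centers)
    return float(np.linalg.norm(est.apply(moving) - centers, axis=1).mean())


@pytest.fixture(scope="module")
def dapi_fixture():
    cfg = small_sim_config(
        n_cells=120,
        image_shape=(512, 512),
        margin_px=60.0,
        noise_sd=0.3,
        cycle_transforms=[(0.0, 0.0, 0.0, 1.0)] * 5,
    )
    gt = generate_ground_truth(cfg)
    from cycifpipe.synthetic import default_panel

    cycles = render_cycles(gt, cfg, default_panel(cfg))
    return cfg, gt, cycles[0]["DAPI"].pixels


class TestAffineTransform:
    def test_singular_matrix_rejected(self):
        with pytest.raises(ParameterError):
            AffineTransform(np.array([[1.0, 0, 0], [2.0, 0, 0]]))

    def test_extreme_determinant_rejected(self):
        with pytest.raises(ParameterError):
            AffineTransform(np.array([[3.0, 0, 0], [0, 3.0, 0]]))

    def test_inverse_compose_is_identity(self):
        t = AffineTransform.from_params((5, -3), 10.0, 1.05, center=(50, 50))
        ident = t.compose(t.inverse()).matrix
        np.testing.assert_allclose(ident, AffineTransform.identity().matrix, atol=1e-9)


class TestEstimateAffine:
    def test_self_registration_returns_identity(self, dapi_fixture):
        _, _, dapi = dapi_fixture
        res = estimate_affine(dapi, dapi)
        assert np.abs(res.transform.translation).max() <= 0.1
        assert np.abs(res.transform.linear - np.eye(2)).max() <= 1e-3

    def test_pure_translation_recovered_within_half_pixel(self, dapi_fixture):
        cfg, gt, dapi = dapi_fixture
        true_t = AffineTransform.from_params((12.0, -7.0))
        moving = warp_array(dapi, true_t.inverse())[0]
        res = estimate_affine(dapi, moving)
        assert np.abs(res.transform.translation - [12.0, -7.0]).max() <= 0.5

    def test_rotation_plus_shift_landmark_error_below_one_pixel(
        self, dapi_fixture
    ):
        cfg, gt, dapi = dapi_fixture
        true_t = AffineTransform.from_params(
            (5.0, 5.0), rotation_deg=2.0, center=center_of(dapi)
        )
        moving = warp_array(dapi, true_t.inverse())[0]
        res = estimate_affine(dapi, moving)
        assert landmark_error(res.transform, true_t, gt.centers[:50]) <= 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(RegistrationError):
            estimate_affine(np.ones((64, 64)), np.ones((64, 64)))

    def test_error_decreases_across_pyramid_levels(self, dapi_fixture):
        cfg, gt, dapi = dapi_fixture
        true_t = AffineTransform.from_params(
            (9.0, -6.0), rotation_deg=1.5, center=center_of(dapi)
        )
        moving = warp_array(dapi, true_t.inverse())[0]
        res = estimate_affine(dapi, moving)
        errs = [
            landmark_error(t, true_t, gt.centers) for t in res.level_transforms
        ]
        assert errs[-1] <= errs[0] + 1e-6
        for a, b in zip(errs, errs[1:]):
            assert b <= a + 0.25  # refinement never substantially regresses


class TestWarp:
    def test_identity_leaves_images_unchanged(self, small_cycles):
        warped, valid = warp(small_cycles[0], AffineTransform.identity())
        assert valid.all()
        for m in small_cycles[0]:
            np.testing.assert_allclose(
                warped[m].pixels, small_cycles[0][m].pixels, atol=1e-9
            )

    def test_round_trip_close_to_original(self, dapi_fixture):
        _, _, dapi = dapi_fixture
        t = AffineTransform.from_params(
            (5.3, -7.7), rotation_deg=2.0, center=center_of(dapi)
        )
        fwd, v1 = warp_array(dapi, t)
        back, v2 = warp_array(fwd, t.inverse())
        both = v1 & v2
        mad = np.abs(back - dapi)[both].mean()
        assert mad <= 0.01 * (dapi.max() - dapi.min())

    def test_translation_invalidates_exactly_the_vacated_rows(self):
        img = np.random.default_rng(0).uniform(0, 1, (64, 64))
        t = AffineTransform.from_params((10.0, 0.0))
        _, valid = warp_array(img, t)
        assert not valid[:10].any()
        assert valid[10:].all()

    def test_pure_translation_conserves_interior_intensity(self, dapi_fixture):
        cfg, gt, _ = dapi_fixture
        from cycifpipe.synthetic import render_scene

        # spots only (no background plane), all >= 60 px from the border,
        # so nothing leaves the frame under a small shift
        img = render_scene(gt, cfg, "DAPI")
        t = AffineTransform.from_params((8.0, -6.0))
        warped, _ = warp_array(img, t)
        assert warped.sum() == pytest.approx(img.sum(), rel=0.01)


class TestAlignExperiment:
    def test_single_cycle_returned_unchanged(self, small_cycles, small_panel):
        res = align_experiment(small_cycles[:1], small_panel)
        assert len(res.cycles) == 1
        np.testing.assert_allclose(
            res.transforms[0].matrix, AffineTransform.identity().matrix
        )

    def test_known_transforms_recovered_on_all_cycles(self):
        cfg = small_sim_config(
            n_cells=120, image_shape=(512, 512), margin_px=60.0, noise_sd=0.3
        )
        from cycifpipe.synthetic import default_panel

        panel = default_panel(cfg)
        gt = generate_ground_truth(cfg)
        cycles = render_cycles(gt, cfg, panel)
        res = align_experiment(cycles, panel)
        for true_t, reg in zip(gt.transforms[1:], res.results[1:]):
            assert landmark_error(reg.transform, true_t, gt.centers) <= 1.0

    def test_aligned_nuclear_channels_strongly_correlated(self):
        cfg = small_sim_config(
            n_cells=120, image_shape=(512, 512), margin_px=60.0, noise_sd=0.0
        )
        from cycifpipe.synthetic import default_panel

        panel = default_panel(cfg)
        gt = generate_ground_truth(cfg)
        cycles = render_cycles(gt, cfg, panel)
        res = align_experiment(cycles, panel)
        ref = res.cycles[0]["DAPI"].pixels
        for cyc, valid in zip(res.cycles[1:], res.validity_masks[1:]):
            moving = cyc["DAPI"].pixels
            corr = np.corrcoef(ref[valid], moving[valid])[0, 1]
            assert corr >= 0.95

    def test_missing_nuclear_channel_rejected(self, small_cycles, small_panel):
        broken = [dict(small_cycles[0]), {"IBA1": small_cycles[1]["IBA1"]}]
        with pytest.raises(ParameterError, match="nuclear"):
            align_experiment(broken, small_panel)


class TestCropCommonRegion:
    def test_all_true_returns_full_frame(self):
        masks = [np.ones((40, 60), bool)] * 3
        assert crop_common_region(masks) == (0, 0, 40, 60)

    def test_translation_crop_height_matches_geometry(self):
        full = np.ones((64, 64), bool)
        shifted = np.ones((64, 64), bool)
        shifted[:10] = False
        r0, c0, r1, c1 = crop_common_region([full, shifted])
        assert (r1 - r0, c1 - c0) == (54, 64)
        assert r0 == 10

    def test_disjoint_masks_raise_cropping_error(self):
        a = np.zeros((32, 32), bool)
        b = np.zeros((32, 32), bool)
        a[:10] = True
        b[20:] = True
        with pytest.raises(CroppingError):
            crop_common_region([a, b])

    def test_matches_brute_force_on_random_masks(self, rng):
        def brute_force(mask):
            best = 0
            nr, nc = mask.shape
            for r0 in range(nr):
                for r1 in range(r0 + 1, nr + 1):
                    for c0 in range(nc):
                        for c1 in range(c0 + 1, nc + 1):
                            if mask[r0:r1, c0:c1].all():
                                best = max(best, (r1 - r0) * (c1 - c0))
            return best

        for _ in range(5):
            mask = rng.uniform(size=(12, 14)) > 0.2
            mask[5, 6] = True  # guarantee non-empty intersection
            r0, c0, r1, c1 = crop_common_region([mask])
            assert mask[r0:r1, c0:c1].all()
            assert (r1 - r0) * (c1 - c0) == brute_force(mask)


class TestAlignBrightfield:
    def test_identical_pairs_give_identity(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [7.0, 3.0]])
        fit = align_brightfield(pts, pts)
        np.testing.assert_allclose(
            fit.transform.matrix, AffineTransform.identity().matrix, atol=1e-12
        )
        assert fit.rms_residual <= 1e-12

    def test_known_affine_recovered_exactly(self):
        true_t = AffineTransform.from_params((3.0, -2.0), 10.0, 1.05)
        src = np.array([[0.0, 0.0], [40.0, 5.0], [10.0, 30.0], [25.0, 25.0]])
        fit = align_brightfield(src, true_t.apply(src))
        np.testing.assert_allclose(fit.transform.matrix, true_t.matrix, atol=1e-9)
        assert fit.rms_residual <= 1e-9

    def test_collinear_points_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ParameterError, match="collinear"):
            align_brightfield(src, src)

    def test_fewer_than_three_pairs_rejected(self):
        src = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ParameterError):
            align_brightfield(src, src)


class TestCompositionConsistency:
    def test_pairwise_estimates_compose(self, dapi_fixture):
        cfg, gt, dapi = dapi_fixture
        t_ab = AffineTransform.from_params((6.0, -4.0), 1.0, center=center_of(dapi))
        t_bc = AffineTransform.from_params((-3.0, 5.0), -1.5, center=center_of(dapi))
        img_b = warp_array(dapi, t_ab.inverse())[0]
        img_c = warp_array(dapi, (t_ab.compose(t_bc)).inverse())[0]
        est_ab = estimate_affine(dapi, img_b).transform
        est_bc = estimate_affine(img_b, img_c).transform
        est_ac = estimate_affine(dapi, img_c).transform
        composed = est_ab.compose(est_bc)
        pts = gt.centers
        err = np.linalg.norm(composed.apply(pts) - est_ac.apply(pts), axis=1)
        assert err.mean() <= 2.0
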