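"""Registration stage: blobs, matching, similarity fitting, RANSAC, warping."""

import math

import numpy as np
import pytest
from skimage import transform as sktransform

from clemalign import (
    CorrespondenceSet,
    ImagePlane,
    RegisterConfig,
    RegistrationStatus,
    SceneParams,
    SimilarityTransform2D,
    apply_transform,
    compose,
    detect_blobs,
    exhaustive_similarity_search,
    fit_similarity,
    invert,
    make_scenes,
    match_keypoints,
    ncc,
    ransac_similarity,
    register_planes,
    render_fluorescence,
)
from clemalign.register import (
    NoConsensusError,
    ReflectionRequiredError,
    warp_valid_mask,
)
from clemalign.evaluate import oracle_predictor


def gaussian_blob_image(centers, sigma=3.0, size=128, amp=1.0):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    for (x, y) in centers:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return ImagePlane(img, 25.0)


def pairs_from_transform(t, points):
    pts = np.asarray(points, dtype=float)
    return CorrespondenceSet(pts, t.apply(pts), np.ones(len(pts)))


class TestDetectBlobs:
    def test_single_gaussian_localized_subpixel(self):
        img = gaussian_blob_image([(40.0, 60.0)], sigma=3.0)
        kps = detect_blobs(img)
        assert len(kps) == 1
        k = kps[0]
        assert math.hypot(k.x_px - 40.0, k.y_px - 60.0) < 0.5
        # LoG optimum for a Gaussian spot: scale ~ sigma*sqrt(2)
        assert k.scale_px / (3.0 * math.sqrt(2)) == pytest.approx(1.0, abs=0.5)

    def test_three_separated_blobs_found(self):
        centers = [(30.0, 30.0), (90.0, 40.0), (50.0, 100.0)]
        kps = detect_blobs(gaussian_blob_image(centers, sigma=3.0))
        assert len(kps) == 3
        found = {
            min(range(3), key=lambda i: math.hypot(k.x_px - centers[i][0], k.y_px - centers[i][1]))
            for k in kps
        }
        assert found == {0, 1, 2}
        for k in kps:
            d = min(math.hypot(k.x_px - cx, k.y_px - cy) for cx, cy in centers)
            assert d < 0.5

    def test_pure_noise_with_high_threshold_empty(self, rng):
        img = ImagePlane(rng.normal(0, 0.01, size=(64, 64)), 25.0)
        cfg = RegisterConfig(blob_threshold=0.9)
        assert detect_blobs(img, cfg) == []

    def test_constant_image_empty(self):
        assert detect_blobs(ImagePlane(np.ones((64, 64)), 25.0)) == []

    def test_sorted_by_response(self):
        img = gaussian_blob_image([(30.0, 30.0)], amp=1.0).pixels
        img += gaussian_blob_image([(90.0, 90.0)], amp=0.5).pixels
        kps = detect_blobs(ImagePlane(img, 25.0))
        assert len(kps) == 2
        assert kps[0].response >= kps[1].response
        assert math.hypot(kps[0].x_px - 30, kps[0].y_px - 30) < 1.0


class TestMatchKeypoints:
    def test_identical_lists_self_match(self):
        kps = detect_blobs(gaussian_blob_image(
            [(30.0, 30.0), (90.0, 40.0), (50.0, 100.0), (100.0, 100.0)], sigma=2.5))
        matches = match_keypoints(kps, kps, 0.8)
        assert len(matches) == len(kps)
        assert np.allclose(matches.moving_xy, matches.fixed_xy)

    def test_permutation_recovered_by_brute_force_agreement(self, rng):
        kps = detect_blobs(gaussian_blob_image(
            [(30.0, 30.0), (90.0, 40.0), (50.0, 100.0), (100.0, 95.0)], sigma=2.5))
        perm = rng.permutation(len(kps))
        shuffled = [kps[i] for i in perm]
        matches = match_keypoints(kps, shuffled, 0.8)
        assert len(matches) == len(kps)
        # brute-force oracle: each moving keypoint's true partner is itself
        for mxy, fxy in zip(matches.moving_xy, matches.fixed_xy):
            assert np.allclose(mxy, fxy)

    def test_ambiguous_duplicate_dropped_by_ratio_test(self):
        kps = detect_blobs(gaussian_blob_image([(40.0, 60.0)], sigma=3.0))
        k = kps[0]
        from dataclasses import replace

        twin_a = replace(k, x_px=80.0)
        twin_b = replace(k, x_px=100.0)
        matches = match_keypoints([k], [twin_a, twin_b], 0.8)
        assert len(matches) == 0

    def test_empty_inputs_give_empty_set(self):
        kps = detect_blobs(gaussian_blob_image([(40.0, 60.0)]))
        assert len(match_keypoints([], kps, 0.8)) == 0
        assert len(match_keypoints(kps, [], 0.8)) == 0


class TestFitSimilarity:
    def test_two_exact_pairs_recover_transform(self):
        t = SimilarityTransform2D(math.radians(30), 1.1, 5.0, -2.0)
        fit = fit_similarity(pairs_from_transform(t, [(0, 0), (10, 0)]))
        assert fit.is_close(t, 1e-9, 1e-9, 1e-9)

    def test_identity_pairs_give_identity(self, rng):
        pts = rng.uniform(0, 100, size=(5, 2))
        fit = fit_similarity(CorrespondenceSet(pts, pts, np.ones(5)))
        assert fit.is_close(SimilarityTransform2D.identity(), 1e-9, 1e-9, 1e-9)

    def test_quarter_turn_with_large_shift_exact(self, rng):
        t = SimilarityTransform2D(math.radians(90), 1.0, 125.0, 0.0)
        pts = rng.uniform(0, 100, size=(10, 2))
        corr = pairs_from_transform(t, pts)
        fit = fit_similarity(corr)
        assert fit.is_close(t, 1e-9, 1e-9, 1e-9)
        residual = np.sum((fit.apply(pts) - corr.fixed_xy) ** 2)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_skimage_on_noisy_pairs(self, rng):
        t = SimilarityTransform2D(0.4, 1.25, -7.0, 3.0)
        pts = rng.uniform(0, 100, size=(20, 2))
        noisy_fix = t.apply(pts) + rng.normal(0, 0.5, size=(20, 2))
        ours = fit_similarity(CorrespondenceSet(pts, noisy_fix, np.ones(20)))
        ref = sktransform.estimate_transform("similarity", pts, noisy_fix)
        assert ours.matrix == pytest.approx(np.asarray(ref.params), abs=1e-9)

    def test_reflection_required_raises(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        flipped = pts.copy()
        flipped[:, 0] *= -1.0  # mirror about the y axis
        with pytest.raises(ReflectionRequiredError):
            fit_similarity(CorrespondenceSet(pts, flipped, np.ones(3)))

    def test_too_few_or_degenerate_pairs(self):
        with pytest.raises(ValueError):
            fit_similarity(CorrespondenceSet(np.zeros((1, 2)), np.zeros((1, 2)), np.ones(1)))
        same = np.tile([[5.0, 5.0]], (4, 1))
        with pytest.raises(ValueError, match="coincide"):
            fit_similarity(CorrespondenceSet(same, np.random.default_rng(0).uniform(size=(4, 2)), np.ones(4)))


class TestRansac:
    def test_all_inliers_equal_full_fit(self, rng):
        t = SimilarityTransform2D(0.2, 1.05, 3.0, -4.0)
        pts = rng.uniform(0, 100, size=(12, 2))
        corr = pairs_from_transform(t, pts)
        est, mask = ransac_similarity(corr, RegisterConfig(seed=1))
        assert mask.all()
        assert est.is_close(fit_similarity(corr), 1e-9, 1e-9, 1e-9)

    def test_outlier_contamination_rejected(self, rng):
        t = SimilarityTransform2D(math.radians(12), 1.03, 20.0, -10.0)
        true_pts = rng.uniform(0, 200, size=(10, 2))
        mov = np.vstack([true_pts, rng.uniform(0, 200, size=(10, 2))])
        fix = np.vstack([t.apply(true_pts), rng.uniform(0, 200, size=(10, 2))])
        corr = CorrespondenceSet(mov, fix, np.ones(20))
        est, mask = ransac_similarity(corr, RegisterConfig(seed=7))
        assert mask.sum() >= 10
        assert abs(est.tx_px - t.tx_px) < 0.1 and abs(est.ty_px - t.ty_px) < 0.1
        assert abs(est.theta_deg - t.theta_deg) < 0.1
        assert abs(est.scale - t.scale) / t.scale < 1e-3

    def test_deterministic_given_seed(self, rng):
        t = SimilarityTransform2D(0.1, 1.0, 5.0, 5.0)
        pts = rng.uniform(0, 100, size=(8, 2))
        corr = CorrespondenceSet(
            pts, t.apply(pts) + rng.normal(0, 0.3, (8, 2)), np.ones(8))
        a, _ = ransac_similarity(corr, RegisterConfig(seed=3))
        b, _ = ransac_similarity(corr, RegisterConfig(seed=3))
        assert a == b

    def test_single_pair_rejected(self):
        corr = CorrespondenceSet(np.zeros((1, 2)), np.zeros((1, 2)), np.ones(1))
        with pytest.raises(ValueError):
            ransac_similarity(corr, RegisterConfig())

    def test_no_consensus_raises(self, rng):
        mov = rng.uniform(0, 500, size=(8, 2))
        fix = rng.uniform(0, 500, size=(8, 2))
        corr = CorrespondenceSet(mov, fix, np.ones(8))
        with pytest.raises(NoConsensusError):
            ransac_similarity(corr, RegisterConfig(seed=0, inlier_tol_px=0.05))


class TestNcc:
    def test_self_correlation_is_one(self, rng):
        a = rng.uniform(size=(32, 32))
        assert ncc(a, a) == pytest.approx(1.0)
        assert ncc(a, -a) == pytest.approx(-1.0)

    def test_matches_hand_computed_value(self):
        a = np.array([[1, 2, 3, 4]] * 4, dtype=float)
        b = np.array([[2, 2, 5, 1]] * 4, dtype=float)
        az, bz = a - a.mean(), b - b.mean()
        expected = (az * bz).sum() / np.sqrt((az**2).sum() * (bz**2).sum())
        assert ncc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_constant_overlap_rejected(self):
        with pytest.raises(ValueError):
            ncc(np.ones((16, 16)), np.random.default_rng(0).uniform(size=(16, 16)))


class TestApplyTransform:
    def test_identity_nearest_is_bitwise(self, rng):
        img = ImagePlane(rng.uniform(size=(48, 48)), 25.0)
        out = apply_transform(img, SimilarityTransform2D.identity(), interp="NEAREST")
        assert np.array_equal(out.pixels, img.pixels)

    def test_integer_shift_matches_array_roll(self, rng):
        img = ImagePlane(rng.uniform(size=(48, 48)), 25.0)
        out = apply_transform(img, SimilarityTransform2D(0, 1, 5, 3), interp="NEAREST")
        assert np.array_equal(out.pixels[3:, 5:], img.pixels[:-3, :-5])
        assert np.all(out.pixels[:3, :] == 0) and np.all(out.pixels[:, :5] == 0)

    def test_round_trip_bilinear_small_error(self):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 5)[0]
        img = render_fluorescence(scene, noiseless=True)
        t = SimilarityTransform2D(math.radians(7), 1.02, 3.5, -2.5)
        back = apply_transform(apply_transform(img, t), t.invert())
        interior = (slice(16, -16), slice(16, -16))
        mad = np.abs(back.pixels[interior] - img.pixels[interior]).mean()
        assert mad < 0.01 * np.ptp(img.pixels)

    def test_intensity_conserved_at_unit_scale(self):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 5)[0]
        img = render_fluorescence(scene, noiseless=True)
        img = ImagePlane(img.pixels - img.pixels.min(), 25.0)
        t = SimilarityTransform2D(math.radians(5), 1.0, 4.0, 3.0)
        out = apply_transform(img, t)
        assert out.pixels.sum() == pytest.approx(img.pixels.sum(), rel=0.02)

    def test_invalid_interp_and_shape(self, rng):
        img = ImagePlane(rng.uniform(size=(32, 32)), 25.0)
        with pytest.raises(ValueError):
            apply_transform(img, SimilarityTransform2D.identity(), interp="CUBIC")
        with pytest.raises(ValueError):
            apply_transform(img, SimilarityTransform2D.identity(), out_shape=(0, 10))

    def test_valid_mask_tracks_border(self):
        mask = warp_valid_mask((32, 32), SimilarityTransform2D(0, 1, 5, 0), (32, 32))
        assert not mask[:, :5].any()
        assert mask[:, 5:].all()


class TestExhaustiveSearch:
    def test_identity_recovered(self, rng):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 6)[0]
        img = render_fluorescence(scene, noiseless=True)
        t = exhaustive_similarity_search(img, img, [0.0], [1.0])
        assert abs(t.tx_px) < 0.5 and abs(t.ty_px) < 0.5

    def test_integer_shift_recovered_exactly(self):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 6)[0]
        img = render_fluorescence(scene, noiseless=True)
        shifted = apply_transform(img, SimilarityTransform2D(0, 1, 17, -9), interp="NEAREST")
        t = exhaustive_similarity_search(img, shifted, [0.0], [1.0])
        assert t.tx_px == pytest.approx(17, abs=0.25)
        assert t.ty_px == pytest.approx(-9, abs=0.25)

    def test_quarter_rotation_selected_from_grid(self):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 6)[0]
        img = render_fluorescence(scene, noiseless=True)
        center = img.center_xy
        rot = apply_transform(
            img, SimilarityTransform2D.about_center(math.radians(90), 1, 0, 0, center))
        t = exhaustive_similarity_search(img, rot, [0.0, 45.0, 90.0, 135.0], [1.0])
        assert t.theta_deg == pytest.approx(90.0, abs=1e-6)

    def test_empty_grid_rejected(self, rng):
        img = ImagePlane(rng.uniform(size=(32, 32)), 25.0)
        with pytest.raises(ValueError):
            exhaustive_similarity_search(img, img, [], [1.0])


class TestRegisterPlanes:
    def test_self_registration_near_identity(self):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 8)[0]
        img = render_fluorescence(scene)
        res = register_planes(img, img)
        assert res.status == RegistrationStatus.OK
        t = res.transform
        assert math.hypot(t.tx_px, t.ty_px) < 0.5
        assert abs(t.theta_deg) < 0.5
        assert abs(t.scale - 1) < 0.01

    def test_large_x_shift_recovered(self):
        """A 3125 nm X-shift (125 px at 25 nm/px) must be recovered sub-pixel."""
        scene = make_scenes(1, SceneParams(), 8)[0]
        fixed = oracle_predictor(scene)
        chrom = render_fluorescence(scene)
        moving = apply_transform(chrom, SimilarityTransform2D(0, 1, 125, 0), interp="NEAREST")
        res = register_planes(moving, fixed)
        assert res.status == RegistrationStatus.OK
        truth = SimilarityTransform2D(0, 1, -125.0, 0.0)
        pts = scene.puncta_xy + np.array([125.0, 0.0])  # landmarks in the moving frame
        err = np.abs(res.transform.apply(pts) - truth.apply(pts))
        assert err.max() < 0.5

    def test_constant_images_low_features(self):
        flat = ImagePlane(np.ones((64, 64)), 25.0)
        res = register_planes(flat, flat)
        assert res.status == RegistrationStatus.LOW_FEATURES

    def test_ok_status_implies_consistent_scores(self):
        scene = make_scenes(1, SceneParams(image_size_px=(128, 128), n_nuclei=1), 9)[0]
        moving = render_fluorescence(scene, apply_misalignment=True)
        fixed = oracle_predictor(scene)
        res = register_planes(moving, fixed)
        if res.status == RegistrationStatus.OK:
            assert res.n_inliers >= 3
            assert res.score_after >= res.score_before


class TestComposeInvert:
    def test_compose_identity_neutral(self):
        t = SimilarityTransform2D(0.3, 1.2, 1.0, 2.0)
        assert compose(SimilarityTransform2D.identity(), t).is_close(t)

    def test_invert_round_trips_random_points(self, rng):
        t = SimilarityTransform2D(math.radians(90), 2.0, 4.0, 0.0)
        pts = rng.uniform(-50, 50, size=(10, 2))
        back = invert(t).apply(t.apply(pts))
        assert np.max(np.abs(back - pts)) <= 1e-9
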