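"""Synthetic correlative scenes: determinism, polarity, geometric ground truth."""

import numpy as np
import pytest

from clemalign import (
    MisalignmentRanges,
    SceneParams,
    make_training_set,
    render_em,
    render_fluorescence,
    sample_scene,
)
from clemalign.simulate import make_scenes

SMALL = SceneParams(image_size_px=(128, 128), n_nuclei=1, seed=3)


def _analytic_gaussian_field(scene, positions):
    """Independent sum-of-Gaussians oracle (explicit per-pixel loop formula)."""
    p = scene.params
    h, w = p.image_size_px
    sigma = p.fluo_psf_sigma_nm / p.pixel_size_nm
    yy, xx = np.mgrid[0:h, 0:w]
    field = np.zeros((h, w))
    for (x, y), amp in zip(positions, scene.puncta[:, 3]):
        field += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return field


def _local_centroid(img, x, y, half=8, threshold=0.0):
    """Intensity-weighted centroid in a local window, background-subtracted.

    ``threshold`` (fraction of the window peak) suppresses residual texture
    around the punctum before weighting — standard thresholded centroiding.
    """
    h, w = img.shape
    y0, y1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    x0, x1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    win = img[y0:y1, x0:x1] - np.median(img[y0:y1, x0:x1])
    win = np.clip(win - threshold * win.max(), 0, None)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    s = win.sum()
    return (xx * win).sum() / s, (yy * win).sum() / s


class TestSampling:
    def test_deterministic_given_seed(self):
        a = sample_scene(SMALL)
        b = sample_scene(SMALL)
        assert np.array_equal(a.puncta, b.puncta)
        assert a.true_transform == b.true_transform
        assert np.array_equal(render_em(a).pixels, render_em(b).pixels)
        assert np.array_equal(
            render_fluorescence(a).pixels, render_fluorescence(b).pixels
        )

    def test_different_seeds_differ(self):
        from dataclasses import replace

        a = sample_scene(SMALL)
        b = sample_scene(replace(SMALL, seed=4))
        assert not np.array_equal(a.puncta, b.puncta)

    def test_at_least_three_puncta(self):
        scene = sample_scene(SMALL)
        assert len(scene.puncta) >= 3

    def test_puncta_minimum_enforced_in_params(self):
        with pytest.raises(ValueError, match="three"):
            SceneParams(puncta_per_nucleus_range=(2, 5))

    def test_puncta_do_not_overlap(self):
        scene = sample_scene(SceneParams(seed=11))
        xy = scene.puncta_xy
        r_px = scene.puncta[:, 2] / scene.params.pixel_size_nm
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert np.all(d > (r_px[:, None] + r_px[None, :]))

    def test_zero_width_misalignment_is_identity(self):
        from dataclasses import replace
        from clemalign import SimilarityTransform2D

        params = replace(
            SMALL,
            misalignment_ranges=MisalignmentRanges((0, 0), (1, 1), (0, 0)),
        )
        scene = sample_scene(params)
        assert scene.true_transform.is_close(SimilarityTransform2D.identity())


class TestRendering:
    def test_em_puncta_darker_than_nucleoplasm(self):
        from dataclasses import replace

        scene = sample_scene(replace(SMALL, em_noise_sd=0.0))
        em = render_em(scene).pixels
        # nucleoplasm level sampled away from puncta, inside the nucleus
        nuc = scene.nuclei[0]
        cx, cy = nuc.center_xy
        far = [
            em[int(cy) + dy, int(cx) + dx]
            for dx in range(-3, 4) for dy in range(-3, 4)
            if all(
                np.hypot(int(cx) + dx - px, int(cy) + dy - py) > 2 * rnm / 25.0 + 3
                for px, py, rnm, _ in scene.puncta
            )
        ]
        nucleoplasm = np.mean(far) if far else em.mean()
        for (x, y, _, _) in scene.puncta:
            assert em[int(round(y)), int(round(x))] < nucleoplasm

    def test_em_punctum_centroids_match_ground_truth(self):
        from dataclasses import replace

        scene = sample_scene(replace(SMALL, em_noise_sd=0.0, em_texture_sd=0.0))
        em = render_em(scene).pixels
        inverted = em.max() - em
        for (x, y, _, _) in scene.puncta:
            cx, cy = _local_centroid(inverted, x, y, half=7, threshold=0.3)
            assert np.hypot(cx - x, cy - y) < 0.5

    def test_fluo_aligned_centroids_match_em_frame(self):
        scene = sample_scene(SMALL)
        img = render_fluorescence(scene, apply_misalignment=False, noiseless=True).pixels
        img = img - scene.params.fluo_background
        for (x, y) in scene.puncta_xy:
            cx, cy = _local_centroid(img, x, y)
            assert np.hypot(cx - x, cy - y) < 0.25

    def test_fluo_pure_shift_displaces_centroids(self):
        from dataclasses import replace

        params = replace(
            SMALL,
            misalignment_ranges=MisalignmentRanges((0, 0), (1, 1), (100, 100)),
        )
        scene = sample_scene(params)  # pure +4 px shift at 25 nm/px
        shifted = render_fluorescence(scene, apply_misalignment=True, noiseless=True).pixels
        for (x, y) in scene.puncta_xy:
            if not (8 <= x + 4 < 120 and 8 <= y + 4 < 120):
                continue
            cx, cy = _local_centroid(shifted - scene.params.fluo_background, x + 4, y + 4)
            assert abs(cx - (x + 4)) < 0.25 and abs(cy - (y + 4)) < 0.25

    def test_noiseless_field_matches_analytic_oracle(self):
        scene = sample_scene(SMALL)
        img = render_fluorescence(scene, noiseless=True).pixels
        oracle = _analytic_gaussian_field(scene, scene.puncta_xy) + scene.params.fluo_background
        r = np.corrcoef(img.ravel(), oracle.ravel())[0, 1]
        assert r > 0.99

    def test_polarity_contract_both_modalities(self):
        from dataclasses import replace

        scene = sample_scene(replace(SMALL, em_noise_sd=0.0))
        em = render_em(scene).pixels
        fl = render_fluorescence(scene, noiseless=True).pixels
        for (x, y) in scene.puncta_xy:
            xi, yi = int(round(x)), int(round(y))
            assert em[yi, xi] < np.median(em)
            assert fl[yi, xi] > np.median(fl)

    def test_true_transform_round_trip(self):
        scene = sample_scene(SceneParams(seed=5))
        mapped = scene.true_transform.apply(scene.puncta_xy)
        back = scene.true_transform.invert().apply(mapped)
        assert np.max(np.abs(back - scene.puncta_xy)) <= 1e-9


class TestTrainingSet:
    def test_pairs_are_aligned_and_reproducible(self):
        params = SceneParams(image_size_px=(128, 128), n_nuclei=1)
        pairs = make_training_set(5, params, seed=9)
        again = make_training_set(5, params, seed=9)
        assert len(pairs) == 5
        for (em, fl), (em2, fl2) in zip(pairs, again):
            assert em.shape == fl.shape == (128, 128)
            assert np.array_equal(em.pixels, em2.pixels)
            assert np.array_equal(fl.pixels, fl2.pixels)

    def test_scenes_are_independent(self):
        params = SceneParams(image_size_px=(128, 128), n_nuclei=1)
        pairs = make_training_set(3, params, seed=9)
        assert not np.array_equal(pairs[0][0].pixels, pairs[1][0].pixels)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            make_training_set(0, SMALL, seed=1)

    def test_make_scenes_deterministic(self):
        a = make_scenes(3, SMALL, seed=2)
        b = make_scenes(3, SMALL, seed=2)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.puncta, s2.puncta)
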