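"""Synthetic correlative scene generator.

Renders paired EM-like and fluorescence-like (SIM-like) images of cell nuclei
from a single ground-truth scene description.  The physics it emulates is the
one property the registration method relies on: heterochromatin puncta are
electron-dense (dark) in EM and Hoechst-bright in fluorescence, so the same
landmarks exist in both modalities with inverted polarity, different blur and
different noise.  Each scene additionally carries a known ground-truth
similarity misalignment between the two modality frames, which makes every
downstream stage testable without real correlative data.

All rendering is a pure function of ``(params, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import ImagePlane, Modality, SimilarityTransform2D

__all__ = [
    "MisalignmentRanges",
    "SceneParams",
    "Nucleus",
    "SyntheticScene",
    "sample_scene",
    "render_em",
    "render_fluorescence",
    "make_scenes",
    "make_training_set",
]


@dataclass(frozen=True)
class MisalignmentRanges:
    """Uniform sampling ranges for the ground-truth modality misalignment."""

    theta_deg: tuple[float, float] = (-10.0, 10.0)
    scale: tuple[float, float] = (0.97, 1.03)
    shift_nm: tuple[float, float] = (-500.0, 500.0)

    def __post_init__(self) -> None:
        for name in ("theta_deg", "scale", "shift_nm"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"misalignment range {name} is not ordered: ({lo}, {hi})")


@dataclass(frozen=True)
class SceneParams:
    """Generator configuration.

    Defaults describe an 8 µm field of view at 25 nm/px containing two
    nuclei with 4–7 heterochromatin puncta each (75–150 nm radius).  The
    field is deliberately much larger than the 3125 nm (125 px) benchmark
    shift so that a shifted field still contains at least three puncta —
    the method's well-posedness condition — and the pixel size makes that
    shift an exact 125 px.
    """

    image_size_px: tuple[int, int] = (320, 320)
    pixel_size_nm: float = 25.0
    n_nuclei: int = 2
    puncta_per_nucleus_range: tuple[int, int] = (4, 7)
    punctum_radius_nm_range: tuple[float, float] = (75.0, 150.0)
    em_noise_sd: float = 0.03
    em_texture_sd: float = 0.05
    fluo_psf_sigma_nm: float = 60.0
    fluo_background: float = 0.05
    fluo_noise_gaussian_sd: float = 0.01
    fluo_poisson_scaling: float = 200.0
    misalignment_ranges: MisalignmentRanges = field(default_factory=MisalignmentRanges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        lo, hi = self.puncta_per_nucleus_range
        if lo < 3:
            raise ValueError(
                "puncta_per_nucleus_range minimum must be >= 3: the registration "
                "problem is only well posed with at least three puncta in the field"
            )
        if lo > hi:
            raise ValueError("puncta_per_nucleus_range is not ordered")
        rlo, rhi = self.punctum_radius_nm_range
        if not (0 < rlo <= rhi):
            raise ValueError("punctum_radius_nm_range must be positive and ordered")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.em_noise_sd < 0 or self.fluo_background < 0:
            raise ValueError("noise and background levels must be >= 0")
        if self.fluo_psf_sigma_nm <= 0:
            raise ValueError("fluo_psf_sigma_nm must be > 0")


@dataclass(frozen=True)
class Nucleus:
    center_xy: tuple[float, float]
    semi_axes_px: tuple[float, float]
    theta_rad: float


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth from which both modality images are rendered.

    ``puncta`` rows are ``(x_px, y_px, radius_nm, intensity)`` in EM-frame
    pixel coordinates.  ``true_transform`` maps EM-frame coordinates into the
    (misaligned) fluorescence frame.
    """

    params: SceneParams
    nuclei: tuple[Nucleus, ...]
    puncta: np.ndarray  # (N, 4)
    true_transform: SimilarityTransform2D

    def __post_init__(self) -> None:
        if len(self.puncta) < 3:
            raise ValueError("a scene must contain at least three puncta")

    @property
    def puncta_xy(self) -> np.ndarray:
        return self.puncta[:, :2]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _point_in_ellipse(rng: np.random.Generator, nuc: Nucleus, shrink: float) -> np.ndarray:
    # uniform in the shrunken ellipse via rejection from the unit disk
    while True:
        u = rng.uniform(-1.0, 1.0, size=2)
        if u @ u <= 1.0:
            break
    a, b = nuc.semi_axes_px
    c, s = math.cos(nuc.theta_rad), math.sin(nuc.theta_rad)
    local = np.array([u[0] * a * shrink, u[1] * b * shrink])
    rot = np.array([[c, -s], [s, c]]) @ local
    return np.array(nuc.center_xy) + rot


def sample_scene(params: SceneParams) -> SyntheticScene:
    """Draw one ground-truth scene (deterministic given ``params.seed``)."""
    h, w = params.image_size_px
    rng = _rng(params.seed, 0)

    # -- nuclei: laid out on a jittered grid so they do not overlap badly
    n = params.n_nuclei
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    nuclei: list[Nucleus] = []
    cell_w, cell_h = w / cols, h / rows
    for i in range(n):
        gx, gy = i % cols, i // cols
        cx = (gx + 0.5) * cell_w + rng.uniform(-0.06, 0.06) * cell_w
        cy = (gy + 0.5) * cell_h + rng.uniform(-0.06, 0.06) * cell_h
        base = 0.36 * min(cell_w, cell_h)
        a = base * rng.uniform(0.85, 1.15)
        b = base * rng.uniform(0.7, 1.0)
        nuclei.append(Nucleus((cx, cy), (a, b), rng.uniform(0, math.pi)))

    # -- puncta: non-overlapping dark/bright landmarks inside the nuclei
    puncta: list[tuple[float, float, float, float]] = []
    for nuc in nuclei:
        count = int(rng.integers(params.puncta_per_nucleus_range[0],
                                 params.puncta_per_nucleus_range[1] + 1))
        placed = 0
        attempts = 0
        max_attempts = 800 * count
        while placed < count:
            if attempts >= max_attempts:
                raise RuntimeError(
                    "could not place the required non-overlapping puncta; "
                    "use a larger image / nuclei or smaller punctum radii"
                )
            attempts += 1
            radius_nm = rng.uniform(*params.punctum_radius_nm_range)
            r_px = radius_nm / params.pixel_size_nm
            p = _point_in_ellipse(rng, nuc, shrink=0.78)
            if not (r_px + 1 <= p[0] <= w - r_px - 2 and r_px + 1 <= p[1] <= h - r_px - 2):
                continue
            ok = True
            for (qx, qy, q_rnm, _) in puncta:
                q_rpx = q_rnm / params.pixel_size_nm
                if math.hypot(p[0] - qx, p[1] - qy) <= r_px + q_rpx + 2.0:
                    ok = False
                    break
            if ok:
                puncta.append((float(p[0]), float(p[1]), float(radius_nm),
                               float(rng.uniform(0.6, 1.0))))
                placed += 1

    # -- ground-truth misalignment, rotation/scale about the image center
    mr = params.misalignment_ranges
    theta = math.radians(rng.uniform(*mr.theta_deg))
    scale = rng.uniform(*mr.scale)
    shift_px = np.array([rng.uniform(*mr.shift_nm), rng.uniform(*mr.shift_nm)]) / params.pixel_size_nm
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    true_t = SimilarityTransform2D.about_center(theta, scale, shift_px[0], shift_px[1], center)

    return SyntheticScene(params, tuple(nuclei), np.array(puncta, dtype=float), true_t)


def _soft_disk(r: np.ndarray, radius_px: float, edge_px: float = 1.2) -> np.ndarray:
    """1 inside the disk, 0 outside, linear ramp of width ``edge_px``."""
    return np.clip((radius_px - r) / edge_px + 0.5, 0.0, 1.0)


def _ellipse_mask(shape: tuple[int, int], nuc: Nucleus, soft_px: float = 2.0) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    c, s = math.cos(nuc.theta_rad), math.sin(nuc.theta_rad)
    dx, dy = xx - nuc.center_xy[0], yy - nuc.center_xy[1]
    u = (c * dx + s * dy) / nuc.semi_axes_px[0]
    v = (-s * dx + c * dy) / nuc.semi_axes_px[1]
    rho = np.sqrt(u * u + v * v)
    # convert the normalized radial excess back to an approximate px distance
    mean_ax = 0.5 * (nuc.semi_axes_px[0] + nuc.semi_axes_px[1])
    return np.clip((1.0 - rho) * mean_ax / soft_px + 0.5, 0.0, 1.0)


def render_em(scene: SyntheticScene) -> ImagePlane:
    """Render the EM modality: textured cytoplasm, darker nucleoplasm, dark puncta.

    Intensities are on a [0, 1]-ish scale.  Additive Gaussian noise of
    standard deviation ``em_noise_sd``; fully deterministic given the scene.
    """
    p = scene.params
    h, w = p.image_size_px
    img = np.full((h, w), 0.58)
    if p.em_texture_sd > 0:
        tex_rng = _rng(p.seed, 1)
        texture = ndimage.gaussian_filter(tex_rng.standard_normal((h, w)), sigma=3.0)
        texture *= p.em_texture_sd / max(texture.std(), 1e-12)
        img = img + texture
    for nuc in scene.nuclei:
        img -= 0.10 * _ellipse_mask((h, w), nuc)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for (x, y, radius_nm, intensity) in scene.puncta:
        r_px = radius_nm / p.pixel_size_nm
        r = np.hypot(xx - x, yy - y)
        img -= (0.25 + 0.15 * intensity) * _soft_disk(r, r_px)
    if p.em_noise_sd > 0:
        img = img + _rng(p.seed, 2).normal(0.0, p.em_noise_sd, size=(h, w))
    return ImagePlane(img, p.pixel_size_nm, Modality.EM, "em")


def fluorescence_field(scene: SyntheticScene, positions_xy: np.ndarray) -> np.ndarray:
    """Noise-free sum-of-Gaussians chromatin field at the given spot centers."""
    p = scene.params
    h, w = p.image_size_px
    sigma_px = p.fluo_psf_sigma_nm / p.pixel_size_nm
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    field = np.zeros((h, w))
    for (x, y), intensity in zip(positions_xy, scene.puncta[:, 3]):
        field += intensity * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma_px**2))
    return field


def render_fluorescence(
    scene: SyntheticScene,
    apply_misalignment: bool = False,
    noiseless: bool = False,
) -> ImagePlane:
    """Render the chromatin fluorescence modality.

    Puncta appear as bright Gaussian spots (PSF sigma ``fluo_psf_sigma_nm``)
    over a constant background.  With ``apply_misalignment`` the spot centers
    are mapped through the scene's ground-truth transform (EM frame ->
    fluorescence frame); otherwise the image is pixel-aligned with the EM
    render.  Noise is scaled-Poisson (shot) plus Gaussian (read) unless
    ``noiseless`` is set.
    """
    p = scene.params
    positions = scene.puncta_xy
    if apply_misalignment:
        positions = scene.true_transform.apply(positions)
    img = fluorescence_field(scene, positions) + p.fluo_background
    if not noiseless:
        rng = _rng(p.seed, 3 + int(bool(apply_misalignment)))
        if p.fluo_poisson_scaling > 0:
            img = rng.poisson(np.clip(img, 0, None) * p.fluo_poisson_scaling) / p.fluo_poisson_scaling
        if p.fluo_noise_gaussian_sd > 0:
            img = img + rng.normal(0.0, p.fluo_noise_gaussian_sd, size=img.shape)
    return ImagePlane(img, p.pixel_size_nm, Modality.FLUO, "chromatin")


def make_scenes(n: int, params: SceneParams, seed: int) -> list[SyntheticScene]:
    """Draw ``n`` independent scenes with seeds derived from a master seed."""
    if n < 1:
        raise ValueError("need at least one scene")
    children = np.random.SeedSequence(int(seed)).spawn(n)
    scenes = []
    for child in children:
        scene_seed = int(child.generate_state(1)[0] % (2**31))
        scenes.append(sample_scene(replace(params, seed=scene_seed)))
    return scenes


def make_training_set(
    n_pairs: int, params: SceneParams, seed: int
) -> list[tuple[ImagePlane, ImagePlane]]:
    """Render ``n_pairs`` independent aligned (EM, chromatin) training pairs.

    Each pair comes from its own scene with the misalignment *not* applied —
    the synthetic analogue of manually registered ground-truth image pairs.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return [
        (render_em(s), render_fluorescence(s, apply_misalignment=False))
        for s in make_scenes(n_pairs, params, seed)
    ]
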