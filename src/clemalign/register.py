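"""Similarity-transform registration of a measured chromatin image to a
predicted chromatin image.

The pipeline mirrors what correlation/feature-based slice registration tools
do internally, specialized to punctate chromatin signal:

1. multiscale Laplacian-of-Gaussian blob detection with sub-pixel refinement
   (heterochromatin puncta are the implicit fiducials),
2. rotation-invariant radial descriptors + ratio-test mutual matching,
3. robust closed-form similarity fit (Umeyama, no reflection) inside RANSAC,
4. optional local refinement maximizing zero-normalized cross-correlation,
5. an exhaustive rotation/scale grid search with FFT translation estimation
   as fallback (and as an independent oracle for the feature path).

Estimated transforms map MOVING coordinates into the FIXED frame; warping the
moving image uses the inverse map.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage, optimize
from skimage import transform as sktransform
from skimage.feature import blob_log

from .core import (
    CorrespondenceSet,
    ImagePlane,
    Modality,
    RegistrationResult,
    RegistrationStatus,
    SimilarityTransform2D,
)

__all__ = [
    "Keypoint",
    "RegisterConfig",
    "RegistrationError",
    "ReflectionRequiredError",
    "NoConsensusError",
    "detect_blobs",
    "match_keypoints",
    "fit_similarity",
    "ransac_similarity",
    "ncc",
    "apply_transform",
    "warp_valid_mask",
    "exhaustive_similarity_search",
    "register_planes",
    "compose",
    "invert",
]


class RegistrationError(RuntimeError):
    """Base class for registration failures."""


class ReflectionRequiredError(RegistrationError):
    """The least-squares orthogonal factor is a reflection, which the
    similarity model (rotation + isotropic scale, no flips) excludes."""


class NoConsensusError(RegistrationError):
    """RANSAC could not find a consensus of at least ``min_inliers`` pairs."""


@dataclass(frozen=True)
class Keypoint:
    """A detected blob: sub-pixel position, scale, strength, and descriptor."""

    x_px: float
    y_px: float
    scale_px: float
    response: float
    descriptor: np.ndarray

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_px, self.y_px])


class Refine(str, enum.Enum):
    NONE = "NONE"
    NCC_LOCAL = "NCC_LOCAL"


class Fallback(str, enum.Enum):
    NONE = "NONE"
    EXHAUSTIVE = "EXHAUSTIVE"


@dataclass(frozen=True)
class RegisterConfig:
    """Registration parameters (defaults tuned for punctate chromatin)."""

    detector: str = "LOG_BLOBS"
    n_scales: int = 8
    min_sigma_px: float = 1.5
    max_sigma_px: float = 8.0
    blob_threshold: float = 0.05
    max_keypoints: int = 200
    match_ratio: float = 0.8
    ransac_iters: int = 2000
    inlier_tol_px: float = 3.0
    min_inliers: int = 3
    refine: Refine = Refine.NCC_LOCAL
    fallback: Fallback = Fallback.EXHAUSTIVE
    fallback_theta_step_deg: float = 3.0
    fallback_scale_grid: tuple[float, ...] = (0.95, 1.0, 1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "refine", Refine(self.refine))
        object.__setattr__(self, "fallback", Fallback(self.fallback))
        if not (0.0 < self.match_ratio < 1.0):
            raise ValueError("match_ratio must be in (0, 1)")
        if self.inlier_tol_px <= 0:
            raise ValueError("inlier_tol_px must be > 0")
        if self.min_inliers < 3:
            raise ValueError("min_inliers must be >= 3")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["refine"] = self.refine.value
        d["fallback"] = self.fallback.value
        d["fallback_scale_grid"] = list(self.fallback_scale_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegisterConfig":
        d = dict(d)
        if "fallback_scale_grid" in d:
            d["fallback_scale_grid"] = tuple(d["fallback_scale_grid"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Blob detection
# ---------------------------------------------------------------------------

def _as_array(img) -> np.ndarray:
    return img.pixels if isinstance(img, ImagePlane) else np.asarray(img, dtype=float)


def _minmax01(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def _quadratic_offset(fm: float, f0: float, fp: float) -> float:
    denom = fm - 2.0 * f0 + fp
    if denom >= 0 or abs(denom) < 1e-30:
        return 0.0
    off = 0.5 * (fm - fp) / denom
    return float(np.clip(off, -1.0, 1.0))


def _radial_descriptor(
    img: np.ndarray, x: float, y: float, scale_px: float,
    n_rings: int = 14, n_angles: int = 32,
) -> np.ndarray:
    """Rotation-invariant descriptor: per-ring mean and spread of intensity.

    Rings reach out to 12x the keypoint scale so the descriptor encodes the
    surrounding blob constellation, not just the (often near-identical) local
    spot profile; ring statistics are invariant to rotation about the
    keypoint by construction.
    """
    radii = np.linspace(0.5, 12.0, n_rings) * scale_px
    angles = np.linspace(0.0, 2.0 * math.pi, n_angles, endpoint=False)
    xs = x + radii[:, None] * np.cos(angles)[None, :]
    ys = y + radii[:, None] * np.sin(angles)[None, :]
    samples = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    samples = samples.reshape(n_rings, n_angles)
    desc = np.concatenate([samples.mean(axis=1), samples.std(axis=1)])
    desc = desc - desc.mean()
    norm = np.linalg.norm(desc)
    if norm < 1e-12:
        return np.zeros_like(desc)
    return desc / norm


def detect_blobs(img: ImagePlane | np.ndarray, cfg: RegisterConfig | None = None) -> list[Keypoint]:
    """Detect bright blobs via multiscale LoG with sub-pixel localization.

    Returns keypoints sorted by response (descending).  A constant image
    yields an empty list — the caller decides how to proceed.
    """
    cfg = cfg or RegisterConfig()
    a = _as_array(img)
    if a.max() == a.min():
        return []
    a01 = _minmax01(a)
    raw = blob_log(
        a01,
        min_sigma=cfg.min_sigma_px,
        max_sigma=cfg.max_sigma_px,
        num_sigma=cfg.n_scales,
        threshold=cfg.blob_threshold,
    )
    kps: list[Keypoint] = []
    log_cache: dict[float, np.ndarray] = {}
    h, w = a01.shape
    for (yr, xr, sigma) in raw:
        sigma = float(sigma)
        if sigma not in log_cache:
            # scale-normalized LoG, positive at bright blob centers
            log_cache[sigma] = -(sigma**2) * ndimage.gaussian_laplace(a01, sigma)
        resp = log_cache[sigma]
        yi, xi = int(round(yr)), int(round(xr))
        if not (1 <= yi < h - 1 and 1 <= xi < w - 1):
            continue
        dx = _quadratic_offset(resp[yi, xi - 1], resp[yi, xi], resp[yi, xi + 1])
        dy = _quadratic_offset(resp[yi - 1, xi], resp[yi, xi], resp[yi + 1, xi])
        x, y = xi + dx, yi + dy
        response = float(resp[yi, xi])
        if response <= 0:
            continue
        desc = _radial_descriptor(a01, x, y, sigma)
        kps.append(Keypoint(x, y, sigma * math.sqrt(2.0), response, desc))
    kps.sort(key=lambda k: -k.response)
    return kps[: cfg.max_keypoints]


def match_keypoints(
    moving_kps: list[Keypoint], fixed_kps: list[Keypoint], match_ratio: float = 0.8
) -> CorrespondenceSet:
    """Mutual-nearest-neighbor descriptor matches passing the ratio test."""
    if not moving_kps or not fixed_kps:
        return CorrespondenceSet.empty()
    dm = np.stack([k.descriptor for k in moving_kps])
    df = np.stack([k.descriptor for k in fixed_kps])
    if dm.shape[1] != df.shape[1]:
        raise ValueError("descriptor lengths differ between keypoint lists")
    dist = np.linalg.norm(dm[:, None, :] - df[None, :, :], axis=2)
    nn_f = np.argmin(dist, axis=1)  # best fixed for each moving
    nn_m = np.argmin(dist, axis=0)  # best moving for each fixed
    mov_idx, fix_idx, scores = [], [], []
    for i, j in enumerate(nn_f):
        if nn_m[j] != i:
            continue
        d1 = dist[i, j]
        if dist.shape[1] >= 2:
            row = dist[i].copy()
            row[j] = np.inf
            d2 = row.min()
            if d2 <= 0 or d1 >= match_ratio * d2:
                continue
        mov_idx.append(i)
        fix_idx.append(j)
        scores.append(1.0 / (1.0 + d1))
    if not mov_idx:
        return CorrespondenceSet.empty()
    return CorrespondenceSet(
        np.array([moving_kps[i].xy for i in mov_idx]),
        np.array([fixed_kps[j].xy for j in fix_idx]),
        np.array(scores),
    )


# ---------------------------------------------------------------------------
# Similarity fitting
# ---------------------------------------------------------------------------

def fit_similarity(correspondences: CorrespondenceSet) -> SimilarityTransform2D:
    """Closed-form least-squares similarity fit (rotation + isotropic scale +
    translation, no reflection) via the centered cross-covariance SVD.

    Raises :class:`ReflectionRequiredError` if the optimal orthogonal factor
    is a reflection, and ``ValueError`` on degenerate input (< 2 pairs, or all
    moving points coincident).
    """
    mov = correspondences.moving_xy
    fix = correspondences.fixed_xy
    n = len(mov)
    if n < 2:
        raise ValueError(f"similarity fit requires >= 2 point pairs, got {n}")
    mu_m = mov.mean(axis=0)
    mu_f = fix.mean(axis=0)
    mc = mov - mu_m
    fc = fix - mu_f
    var_m = float((mc**2).sum()) / n
    if var_m < 1e-24:
        raise ValueError("degenerate correspondences: all moving points coincide")
    cov = fc.T @ mc / n
    u, d, vt = np.linalg.svd(cov)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        # with a rank-deficient covariance (e.g. the 2-point minimal sample,
        # collinear points) the SVD sign is arbitrary and a proper rotation
        # still attains the optimum; a reflection is only truly required when
        # the covariance has full rank
        if d[-1] > max(d[0], 1e-300) * 1e-9:
            raise ReflectionRequiredError(
                "best-fit orthogonal factor is a reflection; the similarity "
                "model excludes flips (REFLECTION_REQUIRED)"
            )
        s = np.array([1.0, -1.0])
        r = (u * s) @ vt
        scale = float(d @ s) / var_m
    else:
        r = u @ vt
        scale = float(d.sum()) / var_m
    if scale <= 0:
        raise ValueError("degenerate correspondences: non-positive scale")
    t = mu_f - scale * (r @ mu_m)
    theta = math.atan2(r[1, 0], r[0, 0])
    return SimilarityTransform2D(theta, scale, float(t[0]), float(t[1]))


def _residuals(t: SimilarityTransform2D, corr: CorrespondenceSet) -> np.ndarray:
    return np.linalg.norm(t.apply(corr.moving_xy) - corr.fixed_xy, axis=1)


def ransac_similarity(
    correspondences: CorrespondenceSet, cfg: RegisterConfig | None = None
) -> tuple[SimilarityTransform2D, np.ndarray]:
    """RANSAC similarity estimation: 2-pair minimal samples, inlier consensus
    at ``inlier_tol_px``, final refit on all inliers.

    Deterministic given ``cfg.seed``.  Ties in consensus size are broken by
    lower inlier RMS residual.  Raises :class:`NoConsensusError` if the best
    consensus is smaller than ``min_inliers``.
    """
    cfg = cfg or RegisterConfig()
    n = len(correspondences)
    if n < 2:
        raise ValueError(f"RANSAC requires >= 2 correspondences, got {n}")
    rng = np.random.default_rng(cfg.seed)
    best_mask: np.ndarray | None = None
    best_count = 0
    best_rms = np.inf
    for _ in range(cfg.ransac_iters):
        i, j = rng.choice(n, size=2, replace=False)
        sample = correspondences.subset(np.array([i, j]))
        try:
            cand = fit_similarity(sample)
        except (ReflectionRequiredError, ValueError):
            continue
        res = _residuals(cand, correspondences)
        mask = res <= cfg.inlier_tol_px
        count = int(mask.sum())
        if count < 2:
            continue
        rms = float(np.sqrt(np.mean(res[mask] ** 2)))
        if count > best_count or (count == best_count and rms < best_rms):
            best_count, best_rms, best_mask = count, rms, mask
    if best_mask is None or best_count < cfg.min_inliers:
        raise NoConsensusError(
            f"best consensus {best_count} < min_inliers {cfg.min_inliers}"
        )
    refined = fit_similarity(correspondences.subset(best_mask))
    # one re-consensus pass with the refit transform
    res = _residuals(refined, correspondences)
    mask = res <= cfg.inlier_tol_px
    if int(mask.sum()) >= cfg.min_inliers:
        refined = fit_similarity(correspondences.subset(mask))
        best_mask = mask
    return refined, best_mask


# ---------------------------------------------------------------------------
# Intensity-based scoring, warping, exhaustive search
# ---------------------------------------------------------------------------

def ncc(img_a, img_b, mask: np.ndarray | None = None) -> float:
    """Zero-normalized cross-correlation over the valid-pixel overlap."""
    a = _as_array(img_a)
    b = _as_array(img_b)
    if a.shape != b.shape:
        raise ValueError(f"NCC requires equal shapes, got {a.shape} vs {b.shape}")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        if sel.sum() < 2:
            raise ValueError("NCC overlap is empty (or a single pixel)")
        a, b = a[sel], b[sel]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("NCC undefined for constant overlap")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def apply_transform(
    img: ImagePlane,
    t: SimilarityTransform2D,
    out_shape: tuple[int, int] | None = None,
    interp: str = "BILINEAR",
) -> ImagePlane:
    """Warp ``img`` into the frame that ``t`` maps it into.

    Uses inverse-mapped resampling; pixels that map outside the source are
    filled with 0.  ``interp`` is ``NEAREST`` or ``BILINEAR``.
    """
    if out_shape is None:
        out_shape = img.shape
    h, w = out_shape
    if h < 1 or w < 1:
        raise ValueError(f"invalid out_shape {out_shape}")
    order = {"NEAREST": 0, "BILINEAR": 1}.get(str(interp).upper())
    if order is None:
        raise ValueError(f"unknown interpolation {interp!r} (NEAREST or BILINEAR)")
    inv = np.linalg.inv(t.matrix)
    out = sktransform.warp(
        img.pixels, inverse_map=inv, output_shape=(h, w),
        order=order, mode="constant", cval=0.0, preserve_range=True,
    )
    from dataclasses import replace
    return replace(img, pixels=out)


def warp_valid_mask(
    in_shape: tuple[int, int], t: SimilarityTransform2D, out_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of output pixels whose inverse-mapped source lies in-bounds."""
    h, w = out_shape
    inv = np.linalg.inv(t.matrix)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([xx.ravel(), yy.ravel(), np.ones(h * w)])
    src = inv @ pts
    sx, sy = src[0], src[1]
    ih, iw = in_shape
    ok = (sx >= 0) & (sx <= iw - 1) & (sy >= 0) & (sy <= ih - 1)
    return ok.reshape(h, w)


def _block_mean(a: np.ndarray, factor: int) -> np.ndarray:
    h = (a.shape[0] // factor) * factor
    w = (a.shape[1] // factor) * factor
    return a[:h, :w].reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _corr_peak_shift(c: np.ndarray, shape_fixed, shape_moving) -> tuple[float, float]:
    """Sub-pixel peak of a full cross-correlation surface -> (dx, dy)."""
    peak = np.unravel_index(int(np.argmax(c)), c.shape)
    py, px = peak
    dy = py - (shape_moving[0] - 1)
    dx = px - (shape_moving[1] - 1)
    offy = offx = 0.0
    if 1 <= py < c.shape[0] - 1:
        offy = _quadratic_offset(-c[py - 1, px], -c[py, px], -c[py + 1, px])
    if 1 <= px < c.shape[1] - 1:
        offx = _quadratic_offset(-c[py, px - 1], -c[py, px], -c[py, px + 1])
    return dx + offx, dy + offy


def exhaustive_similarity_search(
    moving: ImagePlane | np.ndarray,
    fixed: ImagePlane | np.ndarray,
    theta_grid_deg,
    scale_grid,
    downsample: int = 1,
) -> SimilarityTransform2D:
    """Brute-force similarity estimation over rotation/scale grids.

    For each grid point the moving image is rotated/scaled about its center,
    the translation is taken from the FFT cross-correlation peak (sub-pixel by
    quadratic fit), and the candidate with the highest zero-normalized
    cross-correlation against the fixed image wins.  Deterministic; intended
    for small images (<= ~256 px) or downsampled inputs, and doubles as the
    independent oracle for the feature-based path.

    ``downsample > 1`` block-averages both images by that integer factor
    before the grid search and rescales the found translation — a coarse
    estimate (to within ~downsample/2 px) meant to be polished by the NCC
    refinement stage.
    """
    theta_grid_deg = np.atleast_1d(np.asarray(theta_grid_deg, dtype=float))
    scale_grid = np.atleast_1d(np.asarray(scale_grid, dtype=float))
    if theta_grid_deg.size == 0 or scale_grid.size == 0:
        raise ValueError("theta and scale grids must be non-empty")
    if downsample > 1:
        mov_full = _as_array(moving)
        fix_full = _as_array(fixed)
        coarse = exhaustive_similarity_search(
            _block_mean(mov_full, downsample), _block_mean(fix_full, downsample),
            theta_grid_deg, scale_grid,
        )
        hd = mov_full.shape[0] // downsample
        wd = mov_full.shape[1] // downsample
        center_ds = np.array([(wd - 1) / 2.0, (hd - 1) / 2.0])
        tc = coarse.apply(center_ds[None])[0] - center_ds
        h, w = mov_full.shape
        return SimilarityTransform2D.about_center(
            coarse.theta_rad, coarse.scale,
            float(tc[0]) * downsample, float(tc[1]) * downsample,
            ((w - 1) / 2.0, (h - 1) / 2.0),
        )
    mov_a = _as_array(moving)
    fix_a = _as_array(fixed)
    mov_img = moving if isinstance(moving, ImagePlane) else ImagePlane(mov_a, 1.0)
    h, w = mov_a.shape
    fh, fw = fix_a.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    fixz = fix_a - fix_a.mean()
    full = (fh + h - 1, fw + w - 1)
    fshape = [sp_fft.next_fast_len(s) for s in full]
    f_fix = sp_fft.rfft2(fixz, fshape)

    best: tuple[float, SimilarityTransform2D] | None = None
    for theta_deg in theta_grid_deg:
        for s in scale_grid:
            rs = SimilarityTransform2D.about_center(
                math.radians(theta_deg), float(s), 0.0, 0.0, center
            )
            warped = apply_transform(mov_img, rs, out_shape=(h, w)).pixels
            wz = warped - warped.mean()
            f_m = sp_fft.rfft2(wz[::-1, ::-1], fshape)
            c = sp_fft.irfft2(f_fix * f_m, fshape)[: full[0], : full[1]]
            dx, dy = _corr_peak_shift(c, (fh, fw), (h, w))
            cand = SimilarityTransform2D(0.0, 1.0, dx, dy).compose(rs)
            wfull = apply_transform(mov_img, cand, out_shape=(fh, fw)).pixels
            mask = warp_valid_mask((h, w), cand, (fh, fw))
            if mask.sum() < 16:
                continue
            try:
                score = ncc(wfull, fix_a, mask)
            except ValueError:
                continue
            if best is None or score > best[0]:
                best = (score, cand)
    if best is None:
        raise RegistrationError("exhaustive search found no valid overlap on the grids")
    return best[1]


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _center_params(t: SimilarityTransform2D, center) -> np.ndarray:
    tc = t.apply(np.array([center]))[0] - np.asarray(center)
    return np.array([t.theta_rad, math.log(t.scale), tc[0], tc[1]])


def _from_center_params(p: np.ndarray, center) -> SimilarityTransform2D:
    return SimilarityTransform2D.about_center(
        float(p[0]), math.exp(float(p[1])), float(p[2]), float(p[3]), center
    )


def _ncc_score(moving: ImagePlane, fixed_a: np.ndarray, t: SimilarityTransform2D) -> float:
    warped = apply_transform(moving, t, out_shape=fixed_a.shape).pixels
    mask = warp_valid_mask(moving.shape, t, fixed_a.shape)
    if mask.sum() < 16:
        return -1.0
    try:
        return ncc(warped, fixed_a, mask)
    except ValueError:
        return -1.0


def _refine_ncc(
    moving: ImagePlane, fixed_a: np.ndarray, t0: SimilarityTransform2D
) -> SimilarityTransform2D:
    fh, fw = fixed_a.shape
    center = ((fw - 1) / 2.0, (fh - 1) / 2.0)
    x0 = _center_params(t0, center)

    def cost(p: np.ndarray) -> float:
        return -_ncc_score(moving, fixed_a, _from_center_params(p, center))

    res = optimize.minimize(
        cost, x0, method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-7, "maxfev": 400},
    )
    return _from_center_params(res.x, center)


def _guided_refit(
    kps_m: list[Keypoint], kps_f: list[Keypoint],
    t: SimilarityTransform2D, tol_px: float, min_pairs: int,
) -> tuple[SimilarityTransform2D, int] | None:
    """One ICP-style polish: match blobs under the current estimate, refit.

    Maps the moving keypoints through ``t``, pairs each with its mutual
    nearest fixed keypoint within ``tol_px``, and re-solves the closed-form
    similarity on those landmark pairs.  Landmark centroids localize to a
    small fraction of a pixel, so this step removes the residual bias of
    intensity-based refinement.
    """
    if len(kps_m) < min_pairs or len(kps_f) < min_pairs:
        return None
    mov = np.array([k.xy for k in kps_m])
    fix = np.array([k.xy for k in kps_f])
    current = t
    for _ in range(2):
        mapped = current.apply(mov)
        d = np.linalg.norm(mapped[:, None, :] - fix[None, :, :], axis=2)
        nn_f = d.argmin(axis=1)
        nn_m = d.argmin(axis=0)
        sel = [
            (i, j) for i, j in enumerate(nn_f)
            if nn_m[j] == i and d[i, j] <= tol_px
        ]
        if len(sel) < min_pairs:
            return None
        pairs = CorrespondenceSet(
            mov[[i for i, _ in sel]], fix[[j for _, j in sel]], np.ones(len(sel))
        )
        try:
            current = fit_similarity(pairs)
        except (ReflectionRequiredError, ValueError):
            return None
    return current, len(sel)


def register_planes(
    moving: ImagePlane, fixed: ImagePlane, cfg: RegisterConfig | None = None
) -> RegistrationResult:
    """Register the moving (measured chromatin) plane to the fixed (predicted
    chromatin) plane.

    Never raises on registration *failure* — a non-OK status is returned
    instead; raises only on invalid inputs.  ``status == OK`` guarantees at
    least three geometric inliers and a cross-correlation that did not
    degrade.
    """
    cfg = cfg or RegisterConfig()
    mov_a = moving.pixels
    fix_a = fixed.pixels
    identity = SimilarityTransform2D.identity()

    if mov_a.max() == mov_a.min() or fix_a.max() == fix_a.min():
        return RegistrationResult(identity, 0, 0.0, 0.0, RegistrationStatus.LOW_FEATURES, "none")

    ch = min(mov_a.shape[0], fix_a.shape[0])
    cw = min(mov_a.shape[1], fix_a.shape[1])
    try:
        score_before = ncc(mov_a[:ch, :cw], fix_a[:ch, :cw])
    except ValueError:
        score_before = 0.0

    kps_m = detect_blobs(moving, cfg)
    kps_f = detect_blobs(fixed, cfg)

    estimate: SimilarityTransform2D | None = None
    method = ""
    failure = RegistrationStatus.LOW_FEATURES
    if len(kps_m) >= cfg.min_inliers and len(kps_f) >= cfg.min_inliers:
        matches = match_keypoints(kps_m, kps_f, cfg.match_ratio)
        if len(matches) >= max(2, cfg.min_inliers - 1):
            try:
                estimate, _ = ransac_similarity(matches, cfg)
                method = "features"
            except (NoConsensusError, ValueError, ReflectionRequiredError):
                failure = RegistrationStatus.NO_CONSENSUS
        else:
            failure = RegistrationStatus.NO_CONSENSUS

    if estimate is None and cfg.fallback == Fallback.EXHAUSTIVE:
        thetas = np.arange(-180.0, 180.0, cfg.fallback_theta_step_deg)
        ds = 1
        while min(mov_a.shape + fix_a.shape) // ds > 200:
            ds *= 2
        try:
            estimate = exhaustive_similarity_search(
                moving, fixed, thetas, cfg.fallback_scale_grid, downsample=ds
            )
            method = "exhaustive"
        except RegistrationError:
            estimate = None

    if estimate is None:
        return RegistrationResult(identity, 0, score_before, score_before, failure, "none")

    candidates = [estimate]
    if cfg.refine == Refine.NCC_LOCAL:
        candidates.append(_refine_ncc(moving, fix_a, estimate))
    scored = [(_ncc_score(moving, fix_a, t), t) for t in candidates]
    score_after, final = max(scored, key=lambda st: st[0])

    # Landmark polish: closed-form refit on mutually matched blob pairs.
    # Intensity-based scores are slightly biased toward sub-pixel offsets
    # (warping smooths noise), so when enough landmarks agree the geometric
    # refit wins over the NCC argmax.
    polished = _guided_refit(kps_m, kps_f, final, cfg.inlier_tol_px, cfg.min_inliers)
    if polished is not None:
        final = polished[0]
        score_after = _ncc_score(moving, fix_a, final)

    # geometric verification: moving keypoints mapped near a fixed keypoint
    n_inliers = 0
    if kps_m and kps_f:
        mapped = final.apply(np.array([k.xy for k in kps_m]))
        fxy = np.array([k.xy for k in kps_f])
        d = np.linalg.norm(mapped[:, None, :] - fxy[None, :, :], axis=2)
        n_inliers = int((d.min(axis=1) <= cfg.inlier_tol_px).sum())

    if n_inliers >= 3 and score_after >= score_before:
        status = RegistrationStatus.OK
    else:
        status = RegistrationStatus.DEGRADED
    return RegistrationResult(final, n_inliers, score_before, score_after, status, method)


def compose(t1: SimilarityTransform2D, t2: SimilarityTransform2D) -> SimilarityTransform2D:
    """Transform mapping ``p -> t1(t2(p))``."""
    return t1.compose(t2)


def invert(t: SimilarityTransform2D) -> SimilarityTransform2D:
    """Inverse transform: ``compose(t, invert(t))`` is the identity."""
    return t.invert()
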