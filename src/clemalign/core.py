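"""Domain types shared by every stage of the CLEM registration workflow.

Coordinate convention (used everywhere in this package):

* pixel indices are 0-based; ``x`` is the column index increasing rightward,
  ``y`` the row index increasing downward;
* a point's coordinates refer to the pixel *center*;
* a :class:`SimilarityTransform2D` acts on ``(x, y)`` points about the origin
  ``(0, 0)`` unless an explicit center is passed (``about_center``);
* stored transforms map MOVING (fluorescence) coordinates into FIXED
  (EM / predicted-chromatin) coordinates.  Warping the moving image into the
  fixed frame therefore uses the *inverse* mapping with interpolation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Modality",
    "ImagePlane",
    "SimilarityTransform2D",
    "CorrespondenceSet",
    "RegistrationStatus",
    "RegistrationResult",
    "TransformRecord",
]


class Modality(str, enum.Enum):
    """Origin of an image plane."""

    EM = "EM"
    FLUO = "FLUO"
    PREDICTED = "PREDICTED"


@dataclass(frozen=True)
class ImagePlane:
    """A 2D intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels
        2D array of finite real intensities (any numeric dtype; stored as
        float64).
    pixel_size_nm
        Physical edge length of one pixel in nanometers, > 0.
    modality
        One of :class:`Modality` (EM, FLUO, PREDICTED).
    channel_name
        Free-text channel label, e.g. ``"chromatin"``.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    modality: Modality = Modality.EM
    channel_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"ImagePlane requires a 2D array, got ndim={px.ndim}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(
                f"ImagePlane requires height and width >= 16, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("ImagePlane intensities must all be finite")
        if not (self.pixel_size_nm > 0):
            raise ValueError(f"pixel_size_nm must be > 0, got {self.pixel_size_nm}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "modality", Modality(self.modality))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def center_xy(self) -> tuple[float, float]:
        """Image center in (x, y) pixel coordinates (pixel-center convention)."""
        h, w = self.pixels.shape
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def with_pixels(self, pixels: np.ndarray, modality: Modality | None = None) -> "ImagePlane":
        """New plane with replaced pixel data, preserving physical metadata."""
        return replace(
            self,
            pixels=pixels,
            modality=self.modality if modality is None else modality,
        )


@dataclass(frozen=True)
class SimilarityTransform2D:
    """2D similarity transform ``p' = scale * R(theta) @ p + t`` (no reflection).

    ``theta_rad`` is the rotation angle in radians (counter-clockwise in the
    x-right / y-down convention this package uses, i.e. visually clockwise),
    ``scale`` the isotropic factor (> 0), and ``(tx_px, ty_px)`` the
    translation in pixels.
    """

    theta_rad: float = 0.0
    scale: float = 1.0
    tx_px: float = 0.0
    ty_px: float = 0.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValueError(f"scale must be > 0, got {self.scale}")
        for name in ("theta_rad", "scale", "tx_px", "ty_px"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "SimilarityTransform2D":
        return cls()

    @classmethod
    def about_center(
        cls,
        theta_rad: float,
        scale: float,
        tx_px: float,
        ty_px: float,
        center_xy: tuple[float, float],
    ) -> "SimilarityTransform2D":
        """Rotation/scaling about ``center_xy`` followed by a translation.

        Returns the equivalent origin-anchored transform
        ``p' = s R (p - c) + c + t``.
        """
        cx, cy = center_xy
        c = np.array([cx, cy])
        a = scale * _rot(theta_rad)
        t = c + np.array([tx_px, ty_px]) - a @ c
        return cls(theta_rad=theta_rad, scale=scale, tx_px=float(t[0]), ty_px=float(t[1]))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform2D":
        """Build from a 3x3 homogeneous matrix (must be a proper similarity)."""
        m = np.asarray(m, dtype=float)
        a = m[:2, :2]
        det = np.linalg.det(a)
        if det <= 0:
            raise ValueError("matrix is not a proper (reflection-free) similarity")
        scale = math.sqrt(det)
        r = a / scale
        if not np.allclose(r @ r.T, np.eye(2), atol=1e-6):
            raise ValueError("matrix is not a similarity (anisotropic or sheared)")
        theta = math.atan2(r[1, 0], r[0, 0])
        return cls(theta_rad=theta, scale=scale, tx_px=float(m[0, 2]), ty_px=float(m[1, 2]))

    # -- algebra ------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        m = np.eye(3)
        m[:2, :2] = self.scale * _rot(self.theta_rad)
        m[0, 2] = self.tx_px
        m[1, 2] = self.ty_px
        return m

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points through the transform."""
        pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
        a = self.scale * _rot(self.theta_rad)
        return pts @ a.T + np.array([self.tx_px, self.ty_px])

    def compose(self, other: "SimilarityTransform2D") -> "SimilarityTransform2D":
        """Return the transform ``p -> self(other(p))``."""
        theta = self.theta_rad + other.theta_rad
        scale = self.scale * other.scale
        t = self.apply(np.array([[other.tx_px, other.ty_px]]))[0]
        return SimilarityTransform2D(theta, scale, float(t[0]), float(t[1]))

    def invert(self) -> "SimilarityTransform2D":
        """Inverse transform: ``compose(t, t.invert())`` is the identity."""
        inv_scale = 1.0 / self.scale
        a_inv = inv_scale * _rot(-self.theta_rad)
        t = -a_inv @ np.array([self.tx_px, self.ty_px])
        return SimilarityTransform2D(-self.theta_rad, inv_scale, float(t[0]), float(t[1]))

    @property
    def theta_deg(self) -> float:
        return math.degrees(self.theta_rad)

    def is_close(
        self,
        other: "SimilarityTransform2D",
        atol_t: float = 1e-9,
        atol_theta: float = 1e-9,
        atol_scale: float = 1e-9,
    ) -> bool:
        dtheta = (self.theta_rad - other.theta_rad + math.pi) % (2 * math.pi) - math.pi
        return (
            abs(dtheta) <= atol_theta
            and abs(self.scale - other.scale) <= atol_scale
            and abs(self.tx_px - other.tx_px) <= atol_t
            and abs(self.ty_px - other.ty_px) <= atol_t
        )


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class CorrespondenceSet:
    """Point correspondences between a moving and a fixed image.

    ``moving_xy[i]`` is matched to ``fixed_xy[i]``; ``scores[i]`` is the match
    quality (higher = better).  May be empty — downstream callers must handle
    the empty case.
    """

    moving_xy: np.ndarray  # (N, 2)
    fixed_xy: np.ndarray  # (N, 2)
    scores: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.moving_xy = np.asarray(self.moving_xy, dtype=float).reshape(-1, 2)
        self.fixed_xy = np.asarray(self.fixed_xy, dtype=float).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        if not (len(self.moving_xy) == len(self.fixed_xy) == len(self.scores)):
            raise ValueError("correspondence arrays must have equal length")
        if len(self.moving_xy) and not (
            np.all(np.isfinite(self.moving_xy)) and np.all(np.isfinite(self.fixed_xy))
        ):
            raise ValueError("correspondence coordinates must be finite")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def empty(cls) -> "CorrespondenceSet":
        return cls(np.empty((0, 2)), np.empty((0, 2)), np.empty(0))

    def subset(self, mask: np.ndarray) -> "CorrespondenceSet":
        return CorrespondenceSet(self.moving_xy[mask], self.fixed_xy[mask], self.scores[mask])


class RegistrationStatus(str, enum.Enum):
    OK = "OK"
    LOW_FEATURES = "LOW_FEATURES"
    NO_CONSENSUS = "NO_CONSENSUS"
    DEGRADED = "DEGRADED"


@dataclass
class RegistrationResult:
    """Outcome of registering a moving plane to a fixed plane.

    ``transform`` maps moving coordinates into the fixed frame.  ``score_before``
    and ``score_after`` are zero-normalized cross-correlations between the fixed
    image and the moving image before / after warping.  ``status == OK`` implies
    ``n_inliers >= 3`` and ``score_after >= score_before``.
    """

    transform: SimilarityTransform2D
    n_inliers: int
    score_before: float
    score_after: float
    status: RegistrationStatus
    method: str = ""

    def __post_init__(self) -> None:
        if self.n_inliers < 0:
            raise ValueError("n_inliers must be >= 0")
        if self.status == RegistrationStatus.OK:
            if self.n_inliers < 3:
                raise ValueError("status OK requires n_inliers >= 3")
            if self.score_after < self.score_before:
                raise ValueError("status OK requires score_after >= score_before")


@dataclass(frozen=True)
class TransformRecord:
    """Serializable transform parameters (the XML payload).

    Angles are stored in degrees for readability; conversion to
    :class:`SimilarityTransform2D` uses radians.
    """

    theta_deg: float
    scale: float
    tx_px: float
    ty_px: float
    pixel_size_nm: float
    moving_name: str = "moving"
    fixed_name: str = "fixed"

    @classmethod
    def from_transform(
        cls,
        t: SimilarityTransform2D,
        pixel_size_nm: float,
        moving_name: str = "moving",
        fixed_name: str = "fixed",
    ) -> "TransformRecord":
        return cls(
            theta_deg=math.degrees(t.theta_rad),
            scale=t.scale,
            tx_px=t.tx_px,
            ty_px=t.ty_px,
            pixel_size_nm=pixel_size_nm,
            moving_name=moving_name,
            fixed_name=fixed_name,
        )

    def to_transform(self) -> SimilarityTransform2D:
        return SimilarityTransform2D(
            theta_rad=math.radians(self.theta_deg),
            scale=self.scale,
            tx_px=self.tx_px,
            ty_px=self.ty_px,
        )
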