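"""Readers and writers: TIFF image planes, transform-parameter XML, RGB overlays.

TIFF pixel sizes are taken from the resolution tags (``XResolution`` +
``ResolutionUnit``, or an ImageJ ``unit`` entry).  A missing pixel size is a
hard error unless the caller passes an explicit override — nanometer-scale
error reporting is meaningless without a known pixel size.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .core import ImagePlane, Modality, TransformRecord

__all__ = [
    "read_image",
    "write_image",
    "read_transform_xml",
    "write_transform_xml",
    "write_overlay",
    "OVERLAY_COLORS",
]

# nm per TIFF resolution unit (tag 296): 2 = inch, 3 = centimeter
_UNIT_NM = {2: 2.54e7, 3: 1.0e7}
# ImageJ-style unit strings -> nm
_IJ_UNIT_NM = {
    "nm": 1.0,
    "nanometer": 1.0,
    "um": 1.0e3,
    "µm": 1.0e3,
    "micron": 1.0e3,
    "micrometer": 1.0e3,
    "mm": 1.0e6,
    "cm": 1.0e7,
    "inch": 2.54e7,
}


def _rational(value) -> float:
    if isinstance(value, tuple):
        num, den = value
        return num / den if den else 0.0
    return float(value)


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    xres_tag = page.tags.get("XResolution")
    if xres_tag is None:
        return None
    px_per_unit = _rational(xres_tag.value)
    if px_per_unit <= 0:
        return None
    unit_nm: float | None = None
    if tif.is_imagej and tif.imagej_metadata:
        unit = str(tif.imagej_metadata.get("unit", "")).strip()
        if unit in _IJ_UNIT_NM:
            unit_nm = _IJ_UNIT_NM[unit]
    if unit_nm is None:
        unit_tag = page.tags.get("ResolutionUnit")
        code = int(getattr(unit_tag, "value", 0) or 0)
        unit_nm = _UNIT_NM.get(code)
    if unit_nm is None:
        return None
    return unit_nm / px_per_unit


def read_image(
    path: str | Path,
    pixel_size_nm_override: float | None = None,
    modality: Modality = Modality.EM,
    channel_name: str = "",
) -> ImagePlane | list[ImagePlane]:
    """Read a grayscale TIFF as one :class:`ImagePlane` (or a list per channel).

    Intensities are converted to float64 *without any rescaling* — a 16-bit
    pixel valued 65535 reads back as 65535.0.  The pixel size comes from the
    TIFF resolution metadata; if the file carries none, an explicit
    ``pixel_size_nm_override`` is required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        photometric = page.photometric
        if photometric == tifffile.PHOTOMETRIC.RGB or (
            data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2])
        ):
            raise ValueError(
                f"{path} is an RGB image; this workflow operates on grayscale "
                "planes (pass individual channels as separate files)"
            )
        pixel_size = _pixel_size_from_tiff(tif)
    if pixel_size_nm_override is not None:
        pixel_size = float(pixel_size_nm_override)
    if pixel_size is None:
        raise ValueError(
            f"{path} carries no resolution metadata; pass an explicit "
            "pixel_size_nm_override (nm/px) — a pixel size is required for "
            "physical error reporting"
        )
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        return ImagePlane(data, pixel_size, modality, channel_name)
    if data.ndim == 3:
        return [
            ImagePlane(data[i], pixel_size, modality, f"{channel_name}[{i}]" if channel_name else f"channel{i}")
            for i in range(data.shape[0])
        ]
    raise ValueError(f"unsupported TIFF dimensionality {data.shape} in {path}")


def write_image(plane: ImagePlane, path: str | Path, dtype=np.float64) -> None:
    """Write a plane as a grayscale TIFF with resolution metadata (px/cm)."""
    path = Path(path)
    px_per_cm = Fraction(1.0e7 / plane.pixel_size_nm).limit_denominator(10**9)
    tifffile.imwrite(
        path,
        np.asarray(plane.pixels, dtype=dtype),
        resolution=((px_per_cm.numerator, px_per_cm.denominator),) * 2,
        resolutionunit="CENTIMETER",
    )


# ---------------------------------------------------------------------------
# Transform XML
# ---------------------------------------------------------------------------

_XML_TAG = "similarity_transform"
_XML_FLOAT_ATTRS = ("theta_deg", "scale", "tx_px", "ty_px", "pixel_size_nm")


def write_transform_xml(record: TransformRecord, path: str | Path) -> None:
    """Write transform parameters to XML.

    Schema::

        <similarity_transform theta_deg="..." scale="..." tx_px="..."
            ty_px="..." pixel_size_nm="..." moving="..." fixed="..."/>

    Decimal attributes are written with 17 significant digits so the record
    round-trips to well below 1e-9 relative error.
    """
    el = ET.Element(_XML_TAG)
    for attr in _XML_FLOAT_ATTRS:
        el.set(attr, format(float(getattr(record, attr)), ".17g"))
    el.set("moving", record.moving_name)
    el.set("fixed", record.fixed_name)
    ET.ElementTree(el).write(path, encoding="unicode", xml_declaration=True)


def read_transform_xml(path: str | Path) -> TransformRecord:
    """Read a transform record written by :func:`write_transform_xml`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transform XML not found: {path}")
    root = ET.parse(path).getroot()
    if root.tag != _XML_TAG:
        raise ValueError(f"expected <{_XML_TAG}> root element, found <{root.tag}>")
    values = {}
    for attr in _XML_FLOAT_ATTRS:
        raw = root.get(attr)
        if raw is None:
            raise ValueError(f"transform XML missing required attribute '{attr}'")
        values[attr] = float(raw)
    return TransformRecord(
        moving_name=root.get("moving", "moving"),
        fixed_name=root.get("fixed", "fixed"),
        **values,
    )


# ---------------------------------------------------------------------------
# Overlay
# ---------------------------------------------------------------------------

#: Tint colors assigned to fluorescence channels, in order.
OVERLAY_COLORS: tuple[tuple[float, float, float], ...] = (
    (0.0, 1.0, 0.0),  # green
    (1.0, 0.0, 1.0),  # magenta
    (0.0, 1.0, 1.0),  # cyan
    (1.0, 1.0, 0.0),  # yellow
    (1.0, 0.5, 0.0),  # orange
)


def _minmax01(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def compose_overlay(em: ImagePlane, channels: Sequence[ImagePlane]) -> np.ndarray:
    """Blend EM (grayscale base) with tinted channels; returns float RGB in [0,1]."""
    for ch in channels:
        if ch.shape != em.shape:
            raise ValueError(
                f"overlay channel shape {ch.shape} does not match EM shape {em.shape}"
            )
    gray = _minmax01(em.pixels)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    for i, ch in enumerate(channels):
        color = np.array(OVERLAY_COLORS[i % len(OVERLAY_COLORS)])
        rgb += _minmax01(ch.pixels)[:, :, None] * color[None, None, :]
    return np.clip(rgb, 0.0, 1.0)


def write_overlay(em: ImagePlane, channels: Sequence[ImagePlane], path: str | Path) -> None:
    """Write an 8-bit RGB overlay (TIFF or PNG, chosen by file extension)."""
    rgb8 = np.round(compose_overlay(em, channels) * 255.0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb8, photometric="rgb")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, rgb8)
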