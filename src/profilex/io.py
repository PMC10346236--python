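"""Raster image I/O and intensity-domain plumbing.

The filtering pipelines operate on three image flavours:

* :class:`RawImage` — pixels as decoded from disk (2-D gray or
  rows x cols x channels, 8-bit).
* :class:`GrayImage` — a 2-D float intensity array tagged with the range it
  lives in (``display-8bit`` for 0–255 data, ``unit-interval`` for [0, 1],
  ``raw-float`` for unbounded signed filter output).
* :class:`DisplayImage` — 8-bit integers ready to be written as PNG.

Raw signed filter outputs are kept separate from display-normalised ones on
purpose: the quality metrics are defined on the raw values, where the
minimum may be negative, and min–max normalisation would silently change
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "RawImage",
    "GrayImage",
    "DisplayImage",
    "ImageDecodeError",
    "LUMA_WEIGHTS",
    "DEFAULT_WORKING_SHAPE",
    "load_image",
    "save_image",
    "to_gray",
    "to_unit_interval",
    "resize_to_working",
    "normalize_for_display",
    "to_display_scale",
]

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Default working geometry (rows, cols) of the Exp pipeline.
DEFAULT_WORKING_SHAPE = (1440, 2560)


class ImageDecodeError(RuntimeError):
    """Raised when a file cannot be decoded as a raster image."""


@dataclass
class RawImage:
    """Pixels as decoded from disk, 2-D gray or rows x cols x channels."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixel array, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3, 4):
            raise ValueError(f"unsupported channel count {self.pixels.shape[2]}")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class GrayImage:
    """2-D real-valued intensity array with a declared value domain.

    ``value_domain`` is one of ``display-8bit`` (values meant as 0–255),
    ``unit-interval`` (values meant as [0, 1]) or ``raw-float`` (unbounded
    signed output of a filter).
    """

    pixels: np.ndarray
    value_domain: str = "display-8bit"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage must be 2-D, got ndim={self.pixels.ndim}")
        if self.value_domain not in ("raw-float", "unit-interval", "display-8bit"):
            raise ValueError(f"unknown value domain {self.value_domain!r}")
        if self.value_domain != "raw-float" and not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"non-finite pixels not allowed in domain {self.value_domain!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DisplayImage:
    """2-D integer array in [0, 255], ready for 8-bit PNG output."""

    pixels: np.ndarray = field(default_factory=lambda: np.zeros((1, 1), dtype=np.uint8))

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("DisplayImage must be 2-D")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("DisplayImage values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)


def load_image(path: str | Path) -> RawImage:
    """Read a JPEG/PNG/TIFF file into a :class:`RawImage`.

    Raises :class:`ImageDecodeError` naming the path if the file is missing
    or cannot be decoded.
    """
    path = Path(path)
    try:
        pixels = np.asarray(iio.imread(path))
    except Exception as exc:  # imageio raises a zoo of types
        raise ImageDecodeError(f"cannot decode image file {path!s}: {exc}") from exc
    return RawImage(pixels=pixels, source_path=str(path))


def save_image(img: DisplayImage | GrayImage | np.ndarray, path: str | Path) -> None:
    """Write an image to disk; 8-bit PNG for display data, float TIFF for raw.

    Raw-float :class:`GrayImage` inputs go to 32-bit float TIFF (the path
    should end in ``.tif``/``.tiff``); everything else is written through
    imageio in the format the extension implies.
    """
    path = Path(path)
    if isinstance(img, GrayImage):
        if img.value_domain == "raw-float":
            import tifffile

            # float64 on disk: mapped coefficients can exceed float32 range
            tifffile.imwrite(path, img.pixels.astype(np.float64))
            return
        img = normalize_for_display(img)
    if isinstance(img, DisplayImage):
        img = img.pixels
    iio.imwrite(path, np.asarray(img))


def to_gray(img: RawImage | GrayImage) -> GrayImage:
    """Convert an image to a single gray channel using BT.601 luma weights.

    Alpha channels are dropped before conversion. Already-gray input passes
    through unchanged, so the operation is idempotent.
    """
    if isinstance(img, GrayImage):
        return img
    px = np.asarray(img.pixels, dtype=float)
    if px.ndim == 2:
        return GrayImage(px, value_domain="display-8bit")
    if px.shape[2] == 1:
        return GrayImage(px[:, :, 0], value_domain="display-8bit")
    rgb = px[:, :, :3]  # drop alpha if present
    w = np.asarray(LUMA_WEIGHTS)
    return GrayImage(rgb @ w, value_domain="display-8bit")


def to_unit_interval(img: GrayImage) -> GrayImage:
    """Rescale a gray image onto [0, 1] by its declared domain."""
    if img.value_domain == "unit-interval":
        return img
    if img.value_domain == "display-8bit":
        return GrayImage(img.pixels / 255.0, value_domain="unit-interval")
    raise ValueError("raw-float images have no declared range; normalise explicitly")


def to_display_scale(img: GrayImage) -> GrayImage:
    """Rescale a unit-interval image onto the 0–255 display scale.

    The filters transform pixel values as read from 8-bit files, so images
    synthesised or degraded on [0, 1] are brought to this scale before
    filtering. This is a pure rescale (x255), not a min–max stretch.
    """
    if img.value_domain == "display-8bit":
        return img
    if img.value_domain == "unit-interval":
        return GrayImage(img.pixels * 255.0, value_domain="display-8bit")
    raise ValueError("raw-float images have no declared range; normalise explicitly")


def resize_to_working(
    img: GrayImage,
    rows: int = DEFAULT_WORKING_SHAPE[0],
    cols: int = DEFAULT_WORKING_SHAPE[1],
) -> GrayImage:
    """Bilinearly resize to the working geometry (default 1440 x 2560)."""
    if rows < 2 or cols < 2:
        raise ValueError(f"target dimensions must be >= 2, got ({rows}, {cols})")
    if img.shape == (rows, cols):
        return GrayImage(img.pixels.copy(), value_domain=img.value_domain)
    out = _sk_resize(
        img.pixels,
        (rows, cols),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return GrayImage(out, value_domain=img.value_domain)


def normalize_for_display(img: GrayImage) -> DisplayImage:
    """Affine min–max map of the finite pixel values onto [0, 255].

    Non-finite pixels become 0; a constant image maps to all-zero (there is
    no contrast to show). Rounding is half-away-from-zero so 63.75 -> 64.
    """
    px = img.pixels
    finite = np.isfinite(px)
    if not finite.any():
        raise ValueError("cannot display an image with no finite pixels")
    lo = px[finite].min()
    hi = px[finite].max()
    if hi == lo:
        return DisplayImage(np.zeros(px.shape, dtype=np.uint8))
    scaled = (px - lo) * (255.0 / (hi - lo))
    scaled[~finite] = 0.0
    return DisplayImage(np.floor(scaled + 0.5).astype(np.uint8))
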