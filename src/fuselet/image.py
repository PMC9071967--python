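"""Canonical image container, raster I/O and registration preconditions.

Every pipeline in the toolkit operates on :class:`Image2D`: a single-channel
2-D intensity raster stored as unit-range floats.  Integer rasters are scaled
by their bit depth on load (8-bit by 255, 16-bit by 65535) and quantized back
only when written, so repeated multiscale processing never accumulates
quantization loss.  Fusion requires co-registered inputs; :func:`make_pair`
refuses shape-mismatched images rather than attempting registration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "Image2D",
    "RegisteredPair",
    "RegistrationError",
    "load_image",
    "save_image",
    "make_pair",
    "normalize",
]

# ITU-R BT.601 luminance weights for RGB -> gray conversion
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class RegistrationError(ValueError):
    """Raised when two images cannot form a registered pair."""


@dataclass(frozen=True)
class Image2D:
    """A single-channel 2-D intensity image.

    Parameters
    ----------
    pixels
        2-D float array.  All values must be finite.  Images produced by
        :func:`load_image` or :func:`normalize` lie in [0, 1]; intermediate
        transform coefficients handled elsewhere may be signed.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"Image2D requires a 2-D array, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"Image2D must be at least 2x2, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must all be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegisteredPair:
    """Two co-registered (identically shaped) images, fusion sources A and B."""

    a: Image2D
    b: Image2D

    def __post_init__(self) -> None:
        if self.a.shape != self.b.shape:
            raise RegistrationError(
                "registration precondition violated: shapes "
                f"{self.a.shape} and {self.b.shape} differ"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3|4) color raster to luminance; pass 2-D through."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[:, :, :3].astype(np.float64) @ _LUMA_WEIGHTS
    raise ValueError(f"unsupported raster shape {arr.shape}")


def load_image(path: str | os.PathLike, bit_depth_policy: str = "auto") -> Image2D:
    """Read a PNG/TIFF raster and return a normalized unit-range image.

    8-bit data is divided by 255, 16-bit by 65535; floating-point rasters are
    assumed already unit-range and clipped.  RGB(A) input is converted to
    luminance with BT.601 weights.
    """
    if bit_depth_policy != "auto":
        raise ValueError(f"unknown bit_depth_policy {bit_depth_policy!r}")
    try:
        raw = iio.imread(os.fspath(path))
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-sized image {path!r}")
    raw = np.asarray(raw)
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
    else:
        scale = 1.0
    px = _to_gray(raw).astype(np.float64) / scale
    if scale == 1.0:
        px = np.clip(px, 0.0, 1.0)
    return Image2D(px)


def save_image(img: Image2D, path: str | os.PathLike, bit_depth: int = 8) -> None:
    """Write an image as 8- or 16-bit grayscale PNG/TIFF.

    Values are clipped to [0, 1] and quantized round-half-up, so a
    load/save round trip is exact to within one quantization step.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    vmax = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    q = np.floor(np.clip(img.pixels, 0.0, 1.0) * vmax + 0.5).astype(dtype)
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            tifffile.imwrite(path, q)
        else:
            iio.imwrite(path, q)
    except Exception as exc:
        raise IOError(f"cannot write image {path!r}: {exc}") from exc


def make_pair(a: Image2D, b: Image2D) -> RegisteredPair:
    """Assemble a registered fusion pair; refuse shape-mismatched inputs."""
    return RegisteredPair(a, b)


def normalize(img: Image2D) -> Image2D:
    """Clip intensities into the unit range.  Idempotent."""
    return Image2D(np.clip(img.pixels, 0.0, 1.0))


def as_array(img: "Image2D | np.ndarray") -> np.ndarray:
    """Accept either an Image2D or a bare 2-D array; return float64 array."""
    if isinstance(img, Image2D):
        return img.pixels
    return np.asarray(img, dtype=np.float64)
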