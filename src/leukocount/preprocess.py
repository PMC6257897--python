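"""Smear image loading and color-space conversion.

Wright-stained leukocyte nuclei are dark purple on a pale red-cell
background.  Separating luma from chroma (YCbCr) concentrates the
nucleus/background contrast, which is why the segmentation stage runs on
the YCbCr image by default.

Two YCbCr variants are provided:

``"full"``
    Full-range BT.601, the JPEG convention: Y, Cb, Cr each span 0..255.
    This is the package default since smear images are typically JPEGs.
``"studio"``
    Studio-range BT.601 (Y in 16..235, chroma in 16..240), as used by
    broadcast video and by :func:`skimage.color.rgb2ycbcr`.

Conversion is done in floating point, rounded half away from zero and
clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .errors import ColorSpaceError, DecodeError, UnsupportedImageError

RGB = "RGB"
YCBCR = "YCbCr"

# Full-range BT.601 forward matrix: [Y, Cb, Cr]^T = M @ [R, G, B]^T + [0, 128, 128]^T
_FWD_FULL = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_INV_FULL = np.linalg.inv(_FWD_FULL)

# Studio-range BT.601 (scaled luma/chroma, offset 16/128/128).
_FWD_STUDIO = np.array(
    [
        [65.481, 128.553, 24.966],
        [-37.797, -74.203, 112.0],
        [112.0, -93.786, -18.214],
    ]
) / 255.0
_INV_STUDIO = np.linalg.inv(_FWD_STUDIO)
_OFFSET_STUDIO = np.array([16.0, 128.0, 128.0])
_OFFSET_FULL = np.array([0.0, 128.0, 128.0])


@dataclass(frozen=True)
class SmearImage:
    """An 8-bit three-channel blood-smear image.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
        Channel intensities; RGB or YCbCr order depending on ``color_space``.
    color_space : {"RGB", "YCbCr"}
    source_path : str or None
        Where the image was read from, if anywhere.
    """

    pixels: np.ndarray
    color_space: str = RGB
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise UnsupportedImageError(
                f"expected an H x W x 3 array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            raise UnsupportedImageError(f"expected uint8 pixels, got {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise UnsupportedImageError("image must be at least 1 x 1")
        if self.color_space not in (RGB, YCBCR):
            raise ColorSpaceError(f"unknown color space {self.color_space!r}")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _quantize(x: np.ndarray) -> np.ndarray:
    return np.clip(_round_half_away(x), 0, 255).astype(np.uint8)


def read_image(path: str) -> SmearImage:
    """Read a PNG/JPG/TIFF smear image as 8-bit RGB.

    16-bit inputs are rescaled to 8 bit (divide by 257, round).  An alpha
    channel, if present, is dropped.  Grayscale images are rejected:
    the pipeline's color machinery is meaningless without chroma.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise DecodeError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise UnsupportedImageError(f"{path}: single-channel images are unsupported")
    if arr.ndim != 3:
        raise UnsupportedImageError(f"{path}: unexpected shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.shape[2] != 3:
        raise UnsupportedImageError(f"{path}: {arr.shape[2]} channels unsupported")
    if arr.dtype == np.uint16:
        arr = _quantize(arr.astype(np.float64) / 257.0)
    elif arr.dtype != np.uint8:
        raise UnsupportedImageError(f"{path}: unsupported dtype {arr.dtype}")
    return SmearImage(pixels=arr, color_space=RGB, source_path=str(path))


def write_image(path: str, img: SmearImage) -> None:
    """Write an image losslessly (use PNG/TIFF for exact round trips)."""
    iio.imwrite(path, img.pixels)


def _convert(px: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    out = px.astype(np.float64) @ matrix.T + offset
    return _quantize(out)


def rgb_to_ycbcr(img: SmearImage, variant: str = "full") -> SmearImage:
    """Convert an RGB smear image to YCbCr.

    Parameters
    ----------
    variant : {"full", "studio"}
        Full-range (JPEG) or studio-range BT.601.

    Achromatic pixels (R=G=B) map to Cb = Cr = 128 in both variants.
    """
    if img.color_space != RGB:
        raise ColorSpaceError("input is already YCbCr")
    fwd, off = _variant_matrices(variant, forward=True)
    return SmearImage(
        pixels=_convert(img.pixels, fwd, off),
        color_space=YCBCR,
        source_path=img.source_path,
    )


def ycbcr_to_rgb(img: SmearImage, variant: str = "full") -> SmearImage:
    """Inverse of :func:`rgb_to_ycbcr` (exact to within quantization)."""
    if img.color_space != YCBCR:
        raise ColorSpaceError("input is not YCbCr")
    inv, off = _variant_matrices(variant, forward=False)
    px = (img.pixels.astype(np.float64) - off) @ inv.T
    return SmearImage(pixels=_quantize(px), color_space=RGB, source_path=img.source_path)


def _variant_matrices(variant: str, forward: bool) -> tuple[np.ndarray, np.ndarray]:
    if variant == "full":
        return (_FWD_FULL if forward else _INV_FULL), _OFFSET_FULL
    if variant == "studio":
        return (_FWD_STUDIO if forward else _INV_STUDIO), _OFFSET_STUDIO
    raise ColorSpaceError(f"unknown YCbCr variant {variant!r}")


def convert_triplet(rgb: tuple[float, float, float], variant: str = "full") -> tuple[float, float, float]:
    """Convert a single RGB triplet to YCbCr, unrounded.

    Used to express color prototypes (fit in RGB) in the working space of
    the segmentation stage.
    """
    fwd, off = _variant_matrices(variant, forward=True)
    y = fwd @ np.asarray(rgb, dtype=np.float64) + off
    return (float(y[0]), float(y[1]), float(y[2]))
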