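"""Shared raster primitives for the segmentation operators.

Images are carried in a thin :class:`RasterImage` wrapper that records the
channel model (``RGB8``, ``HSV8``, ``GRAY8`` or ``FLOAT``), because the
operators downstream are only meaningful on the channel layout they were
designed for.  Binary masks are plain boolean numpy arrays with the same
shape as their source image.

Conventions used throughout the package:

* row-major pixel grids, origin at the top-left, 0-based indices;
* 8-bit channel models store values in [0, 255];
* the HSV model rescales hue from degrees to [0, 255]
  (H8 = degrees x 255/360, rounded half up);
* foreground connectivity is 8-connected, background (hole filling)
  4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, measure, morphology

__all__ = [
    "CHANNEL_MODELS",
    "RasterImage",
    "ChannelModelError",
    "rgb_to_hsv255",
    "blue_green_ratio",
    "gaussian_smooth",
    "clean_mask",
    "largest_component",
    "read_image",
    "write_mask",
]

CHANNEL_MODELS = ("RGB8", "HSV8", "GRAY8", "FLOAT")

#: B/G ratio assigned to pixels with G = 0; larger than any threshold in use,
#: so such pixels always classify as background (zero green is never foliage).
G_ZERO_SENTINEL = 1.0e6


class ChannelModelError(ValueError):
    """Raised when an operation receives an image in the wrong channel model."""


@dataclass(frozen=True)
class RasterImage:
    """A 2-D pixel grid with a declared channel model.

    Parameters
    ----------
    pixels
        ``(rows, cols)`` array for single-channel models, ``(rows, cols, 3)``
        for RGB8/HSV8.  8-bit models are stored as ``uint8``; FLOAT as
        ``float64`` with finite values only.
    channel_model
        One of ``RGB8``, ``HSV8``, ``GRAY8``, ``FLOAT``.
    """

    pixels: np.ndarray
    channel_model: str

    def __post_init__(self) -> None:
        if self.channel_model not in CHANNEL_MODELS:
            raise ChannelModelError(f"unknown channel model {self.channel_model!r}")
        px = np.asarray(self.pixels)
        if self.channel_model in ("RGB8", "HSV8"):
            if px.ndim != 3 or px.shape[2] != 3:
                raise ValueError(f"{self.channel_model} image must be rows x cols x 3")
            px = px.astype(np.uint8, copy=False)
        elif self.channel_model == "GRAY8":
            if px.ndim != 2:
                raise ValueError("GRAY8 image must be rows x cols")
            px = px.astype(np.uint8, copy=False)
        else:  # FLOAT
            if px.ndim != 2:
                raise ValueError("FLOAT image must be rows x cols")
            px = px.astype(np.float64, copy=False)
            if not np.all(np.isfinite(px)):
                raise ValueError("FLOAT image must carry finite values only")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        object.__setattr__(self, "pixels", px)

    @property
    def rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def channel(self, index: int) -> "RasterImage":
        """Extract one channel of a 3-channel image as a GRAY8 image."""
        if self.pixels.ndim != 3:
            raise ChannelModelError("channel() requires a 3-channel image")
        return RasterImage(self.pixels[:, :, index], "GRAY8")

    def require(self, model: str) -> None:
        if self.channel_model != model:
            raise ChannelModelError(
                f"expected a {model} image, got {self.channel_model}"
            )


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def rgb_to_hsv255(img: RasterImage) -> RasterImage:
    """Convert an RGB8 image to HSV with all channels rescaled to [0, 255].

    Hue is mapped from degrees to 8 bits (H8 = deg x 255/360) and rounded
    half up; saturation and value likewise span [0, 255].  Achromatic pixels
    (S = 0) get hue 0 by convention.
    """
    img.require("RGB8")
    hsv = color.rgb2hsv(img.pixels)  # H, S, V all in [0, 1]
    hsv8 = _round_half_up(hsv * 255.0).astype(np.uint8)
    return RasterImage(hsv8, "HSV8")


def blue_green_ratio(img: RasterImage) -> RasterImage:
    """Per-pixel B/G ratio image; G = 0 pixels get a large background sentinel."""
    img.require("RGB8")
    g = img.pixels[:, :, 1].astype(np.float64)
    b = img.pixels[:, :, 2].astype(np.float64)
    ratio = np.full_like(g, G_ZERO_SENTINEL)
    np.divide(b, g, out=ratio, where=g > 0)
    return RasterImage(ratio, "FLOAT")


def gaussian_kernel(size: int, sigma: float = 1.0) -> np.ndarray:
    """Normalized 2-D Gaussian kernel of odd side ``size`` (sum 1)."""
    if size % 2 == 0 or size < 3:
        raise ValueError("kernel size must be odd and >= 3")
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    g1 /= g1.sum()
    return np.outer(g1, g1)


def gaussian_smooth(img: RasterImage, size: int = 5, sigma: float = 1.0) -> RasterImage:
    """Smooth with a normalized ``size x size`` Gaussian, reflect padding."""
    if img.channel_model not in ("GRAY8", "FLOAT"):
        raise ChannelModelError("gaussian_smooth expects a single-channel image")
    k = gaussian_kernel(size, sigma)
    out = ndimage.correlate(img.pixels.astype(np.float64), k, mode="reflect")
    return RasterImage(out, "FLOAT")


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken in favour of the component whose first pixel in
    row-major scan order comes first (labels are assigned in scan order,
    so the smallest label among the tied sizes wins).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return np.zeros_like(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(np.argmax(counts))  # argmax returns the first (smallest) label on ties
    return labels == best


def clean_mask(raw: np.ndarray, element_radius: int = 5) -> np.ndarray:
    """Standard raw-mask cleanup: dilate, fill holes, erode, keep largest object.

    A disk structuring element of the given radius is used for both the
    dilation and the erosion.  Hole filling closes background regions not
    connected to the image border (4-connected background).  The result has
    at most one connected component and may be empty.
    """
    if element_radius < 1:
        raise ValueError("element_radius must be >= 1")
    raw = np.asarray(raw, dtype=bool)
    if not raw.any():
        return np.zeros_like(raw)
    selem = morphology.disk(element_radius)
    dilated = morphology.dilation(raw, selem)
    filled = ndimage.binary_fill_holes(dilated)
    eroded = morphology.erosion(filled, selem)
    return largest_component(eroded)


def read_image(path) -> RasterImage:
    """Read an 8-bit RGB image from JPG/PNG."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return RasterImage(arr.astype(np.uint8), "RGB8")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel PNG with values 0/255."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
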