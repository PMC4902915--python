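"""The eight per-image segmentation operators C1, C2, T1, T2 and E1-E4.

Each operator turns the input image into a *raw* binary mask by thresholding
a derived quantity, then refines it with the standard cleanup sequence
(dilate, fill holes, erode, keep largest object; see
:func:`ryeview.imaging.clean_mask`):

====  ======================================================================
C1    HSV colour windows: H in [35, 100], S in [50, 255], V in [40, 226]
C2    blue/green ratio below 0.625 (plant foliage is green-dominant)
T1    FFT low-pass (raised-cosine, radius 25 frequency px) of the S channel,
      intensities above 110
T2    local Shannon entropy of the S channel in a 100 x 100 neighbourhood,
      above 4.7 bits
E1    5x5 Gaussian smoothing, Prewitt gradient magnitude (L2), above 29
E2    5x5 Gaussian smoothing, 3x3 convolution (centre weight 15, others 1)
      divided by 13 and clipped to [0, 255], at or above 230
E3    5x5 Gaussian smoothing, Prewitt gradient (L1 norm), above 27
E4    5x5 Gaussian smoothing, Prewitt gradient (L2) above 15, thinned to
      1-px edge curves, then binarized at >= 1
====  ======================================================================

Threshold semantics: range bounds are inclusive; a scalar threshold t means
strictly greater than t, except E2 where the comparison is >= because
clipping makes 255 a mass point.  The edge operators produce closed edge
rings around the plant; the cleanup's hole filling turns those rings into
filled objects.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import thin as _thin

from .imaging import (
    RasterImage,
    blue_green_ratio,
    clean_mask,
    gaussian_smooth,
    rgb_to_hsv255,
)

__all__ = [
    "METHOD_NAMES",
    "SegmentationConfig",
    "MaskSet",
    "segment_c1",
    "segment_c2",
    "segment_t1",
    "segment_t2",
    "segment_e1",
    "segment_e2",
    "segment_e3",
    "segment_e4",
    "segment_all",
    "local_entropy",
    "prewitt_gradient",
]

logger = logging.getLogger(__name__)

METHOD_NAMES = ("C1", "C2", "T1", "T2", "E1", "E2", "E3", "E4")

#: camera scale at which the default structuring-element radius (5 px) applies
REFERENCE_PIXELS_PER_CM = 74.36


@dataclass(frozen=True)
class SegmentationConfig:
    """Operator thresholds and structural parameters.

    Defaults are a field-calibrated operating point for images at
    ~74 px/cm.  ``element_radius`` is the
    disk radius of the cleanup structuring element and should be scaled
    with the image resolution (:meth:`for_scale`).
    """

    c1_h: tuple[int, int] = (35, 100)   # inclusive hue window (HSV8 units)
    c1_s: tuple[int, int] = (50, 255)   # inclusive saturation window
    c1_v: tuple[int, int] = (40, 226)   # inclusive value window
    c2_ratio_max: float = 0.625         # B/G strictly below -> plant
    t1_radius: float = 25.0             # half-amplitude radius, frequency px
    t1_threshold: float = 110.0         # strictly above -> plant
    t2_window: int = 100                # entropy neighbourhood side, px
    t2_threshold: float = 4.7           # bits, strictly above -> plant
    gauss_size: int = 5                 # Gaussian pre-smoothing kernel side
    gauss_sigma: float = 1.0
    e1_threshold: float = 29.0          # L2 Prewitt magnitude, strictly above
    e2_center: float = 15.0             # centre weight of the 3x3 kernel
    e2_scale: float = 13.0              # divisor applied after convolution
    e2_threshold: float = 230.0         # >= after clipping to [0, 255]
    e3_threshold: float = 27.0          # L1 Prewitt magnitude, strictly above
    e4_threshold: float = 15.0          # L2 Prewitt magnitude, strictly above
    e4_binarize: float = 1.0            # >= on the thinned edge image
    element_radius: int = 5             # cleanup disk radius, px
    entropy_stride: int = 1             # 1 = exact sliding window; k > 1 = strided

    def __post_init__(self) -> None:
        for name in ("c1_h", "c1_s", "c1_v"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} window has lo > hi")
        if self.gauss_size % 2 == 0 or self.gauss_size < 3:
            raise ValueError("gauss_size must be odd and >= 3")
        if self.element_radius < 1:
            raise ValueError("element_radius must be >= 1")
        if self.entropy_stride < 1:
            raise ValueError("entropy_stride must be >= 1")

    @classmethod
    def for_scale(cls, pixels_per_cm: float, **overrides) -> "SegmentationConfig":
        """Config with the cleanup element scaled to the image resolution."""
        radius = max(1, round(5 * pixels_per_cm / REFERENCE_PIXELS_PER_CM))
        overrides.setdefault("element_radius", radius)
        return cls(**overrides)

    def to_flat_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                d[f"{f.name}_lo"], d[f"{f.name}_hi"] = v
            else:
                d[f.name] = v
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "SegmentationConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if isinstance(getattr(cls, f.name), tuple):
                lo, hi = d.get(f"{f.name}_lo"), d.get(f"{f.name}_hi")
                if lo is not None and hi is not None:
                    kwargs[f.name] = (int(lo), int(hi))
            elif f.name in d:
                kwargs[f.name] = type(getattr(cls, f.name))(d[f.name])
        return cls(**kwargs)


@dataclass
class MaskSet:
    """The eight named method masks for one image."""

    masks: dict[str, np.ndarray]
    image_id: str = ""

    def __post_init__(self) -> None:
        if set(self.masks) != set(METHOD_NAMES):
            raise ValueError(f"MaskSet requires exactly the methods {METHOD_NAMES}")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError("all masks in a MaskSet must share one shape")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


def _finish(raw: np.ndarray, cfg: SegmentationConfig, clean: bool) -> np.ndarray:
    return clean_mask(raw, cfg.element_radius) if clean else raw


# ---------------------------------------------------------------- colour ----

def segment_c1(hsv: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Colour-window threshold on an HSV8 image (inclusive bounds)."""
    hsv.require("HSV8")
    h, s, v = (hsv.pixels[:, :, i].astype(np.int64) for i in range(3))
    raw = (
        (h >= cfg.c1_h[0]) & (h <= cfg.c1_h[1])
        & (s >= cfg.c1_s[0]) & (s <= cfg.c1_s[1])
        & (v >= cfg.c1_v[0]) & (v <= cfg.c1_v[1])
    )
    return _finish(raw, cfg, clean)


def segment_c2(rgb: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Blue/green ratio threshold on an RGB8 image (ratio strictly below)."""
    rgb.require("RGB8")
    ratio = blue_green_ratio(rgb).pixels
    raw = ratio < cfg.c2_ratio_max
    return _finish(raw, cfg, clean)


# --------------------------------------------------------------- texture ----

def cosine_lowpass(img: RasterImage, radius: float) -> RasterImage:
    """Frequency-domain raised-cosine low-pass.

    The filter has unit gain at DC, half amplitude at the given radius (in
    centred-spectrum frequency pixels) and reaches zero at twice the radius.
    """
    a = img.pixels.astype(np.float64)
    rows, cols = a.shape
    fy = np.fft.fftfreq(rows) * rows
    fx = np.fft.fftfreq(cols) * cols
    r = np.hypot(fy[:, None], fx[None, :])
    gain = np.where(r <= 2 * radius, 0.5 * (1.0 + np.cos(np.pi * r / (2 * radius))), 0.0)
    out = np.fft.ifft2(np.fft.fft2(a) * gain).real
    return RasterImage(out, "FLOAT")


def segment_t1(s_channel: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Frequency-domain texture operator on the saturation channel."""
    low = cosine_lowpass(s_channel, cfg.t1_radius)
    raw = low.pixels > cfg.t1_threshold
    return _finish(raw, cfg, clean)


def local_entropy(img: RasterImage, window: int, stride: int = 1) -> RasterImage:
    """Shannon entropy (bits, 256-bin histogram) of the square window
    centred on each pixel, reflect padding at the borders.

    ``stride`` > 1 evaluates the exact windowed entropy on a stride-k grid
    and fills the gaps by nearest-neighbour upsampling — an approximation
    trading resolution for speed; the default (1) is exact at every pixel.
    """
    if window < 2:
        raise ValueError("entropy window must be >= 2")
    a = img.pixels
    if a.dtype != np.uint8:
        raise ValueError("local_entropy expects an 8-bit single-channel image")
    half = window // 2
    before, after = half, window - half - 1  # window spans [i-half, i+window-half-1]
    if stride == 1:
        padded = np.pad(a, ((before, after), (before, after)), mode="reflect")
        ent = _rank_entropy(padded, np.ones((window, window), dtype=bool))
        out = ent[before : before + a.shape[0], before : before + a.shape[1]]
        return RasterImage(np.ascontiguousarray(out), "FLOAT")
    return RasterImage(_entropy_strided(a, window, stride), "FLOAT")


def _entropy_strided(a: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Exact windowed entropy on a strided grid via per-bin integral images."""
    rows, cols = a.shape
    half = window // 2
    before, after = half, window - half - 1
    padded = np.pad(a, ((before, after), (before, after)), mode="reflect")
    rr = np.arange(0, rows, stride)
    cc = np.arange(0, cols, stride)
    total = float(window * window)
    ent = np.zeros((rr.size, cc.size), dtype=np.float64)
    for b in np.unique(padded):
        m = padded == b
        s = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(m, axis=0), axis=1, out=s[1:, 1:])
        cnt = (
            s[np.ix_(rr + window, cc + window)]
            - s[np.ix_(rr, cc + window)]
            - s[np.ix_(rr + window, cc)]
            + s[np.ix_(rr, cc)]
        )
        p = cnt / total
        logp = np.zeros_like(p)
        np.log2(p, out=logp, where=p > 0)
        ent -= p * logp
    # nearest-neighbour upsample back to full resolution
    up = np.repeat(np.repeat(ent, stride, axis=0), stride, axis=1)
    return up[:rows, :cols]


def segment_t2(s_channel: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Entropy texture operator on the saturation channel."""
    ent = local_entropy(s_channel, cfg.t2_window, cfg.entropy_stride)
    raw = ent.pixels > cfg.t2_threshold
    return _finish(raw, cfg, clean)


# ------------------------------------------------------------------ edge ----

def prewitt_gradient(img: RasterImage, norm: str = "L2") -> RasterImage:
    """Prewitt gradient magnitude, combining the axis responses by L2 or L1."""
    if img.channel_model not in ("GRAY8", "FLOAT"):
        raise ValueError("prewitt_gradient expects a single-channel image")
    a = img.pixels.astype(np.float64)
    gy = ndimage.prewitt(a, axis=0, mode="reflect")
    gx = ndimage.prewitt(a, axis=1, mode="reflect")
    if norm == "L2":
        mag = np.hypot(gx, gy)
    elif norm == "L1":
        mag = np.abs(gx) + np.abs(gy)
    else:
        raise ValueError("norm must be 'L2' or 'L1'")
    return RasterImage(mag, "FLOAT")


def _smoothed(s_channel: RasterImage, cfg: SegmentationConfig) -> RasterImage:
    return gaussian_smooth(s_channel, cfg.gauss_size, cfg.gauss_sigma)


def segment_e1(s_channel: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Gradient-magnitude edge operator (L2 Prewitt)."""
    mag = prewitt_gradient(_smoothed(s_channel, cfg), "L2")
    raw = mag.pixels > cfg.e1_threshold
    return _finish(raw, cfg, clean)


def segment_e2(s_channel: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Centre-weighted 3x3 convolution operator."""
    kernel = np.ones((3, 3), dtype=np.float64)
    kernel[1, 1] = cfg.e2_center
    conv = ndimage.correlate(_smoothed(s_channel, cfg).pixels, kernel, mode="reflect")
    scaled = np.clip(conv / cfg.e2_scale, 0.0, 255.0)
    raw = scaled >= cfg.e2_threshold
    return _finish(raw, cfg, clean)


def segment_e3(s_channel: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Edge-detect operator for areas of high slope (L1 Prewitt)."""
    mag = prewitt_gradient(_smoothed(s_channel, cfg), "L1")
    raw = mag.pixels > cfg.e3_threshold
    return _finish(raw, cfg, clean)


def segment_e4(s_channel: RasterImage, cfg: SegmentationConfig, clean: bool = True) -> np.ndarray:
    """Refined-edge operator: threshold, thin to 1-px curves, binarize."""
    mag = prewitt_gradient(_smoothed(s_channel, cfg), "L2")
    edges = mag.pixels > cfg.e4_threshold
    thinned = _thin(edges)
    raw = thinned.astype(np.uint8) >= cfg.e4_binarize
    return _finish(raw, cfg, clean)


# ----------------------------------------------------------------- batch ----

_OPERATORS = {
    "C1": ("hsv", segment_c1),
    "C2": ("rgb", segment_c2),
    "T1": ("s", segment_t1),
    "T2": ("s", segment_t2),
    "E1": ("s", segment_e1),
    "E2": ("s", segment_e2),
    "E3": ("s", segment_e3),
    "E4": ("s", segment_e4),
}


def segment_all(
    rgb: RasterImage,
    cfg: SegmentationConfig | None = None,
    image_id: str = "",
) -> MaskSet:
    """Run all eight operators on one RGB image.

    C1 works on the HSV conversion, C2 on the RGB image itself, and the
    texture/edge operators on the saturation channel.  A single operator
    failure never aborts the set: the offending method gets an empty mask
    and the failure is logged.
    """
    rgb.require("RGB8")
    cfg = cfg or SegmentationConfig()
    hsv = rgb_to_hsv255(rgb)
    inputs = {"rgb": rgb, "hsv": hsv, "s": hsv.channel(1)}
    masks: dict[str, np.ndarray] = {}
    for name, (source, op) in _OPERATORS.items():
        try:
            masks[name] = op(inputs[source], cfg)
        except Exception:  # noqa: BLE001 - isolation policy: log and continue
            logger.exception("segmentation method %s failed on image %s", name, image_id)
            masks[name] = np.zeros(rgb.shape, dtype=bool)
    return MaskSet(masks, image_id=image_id)
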