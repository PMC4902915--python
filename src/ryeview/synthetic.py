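"""Seeded generator of field-like top-view scenes with exact ground truth.

The generator emulates the imaging conditions the segmentation pipeline was
designed for: a single spaced perennial-ryegrass plant — a tuft of thin,
curved, tapering green leaves radiating from a centre — photographed from
above against brown soil, with nuisance structure that makes single-method
segmentation fragile in the field:

* multi-octave soil texture and a moisture gradient (soil colour varies);
* algae patches sharing the plant's green hue but with a finer texture
  scale, and small green weed speckles (colour methods over-select these);
* optional yellow-brown leaf sectors, as seen just after cutting
  (colour methods under-select these; edge/texture methods do not care);
* global illumination gain and per-channel white-balance shifts.

The ground-truth mask is exactly the rasterized union of the drawn leaves
(brown sectors included); algae and weeds are background.  All randomness
derives from the seed in the parameters, so scenes are bit-reproducible.

Scenes default to 512 x 512 px at 74.36/4 ~ 18.6 px/cm — full-resolution
field optics (74.36 px/cm) downsampled 4x with a plant-centred crop.
"""

from __future__ import annotations

import colorsys
import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import RasterImage

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "generate_scene",
    "scene_for_area",
    "generate_growth_series",
    "generate_temperature_series",
]

#: cuts of the first growing season: labels and cumulative thermal time
#: (°C·day) at the cut, ~6-week intervals at a ~15 °C daily mean
DEFAULT_CUTS = (("Y1C2", 0.0), ("Y1C3", 650.0), ("Y1C4", 1300.0), ("Y1C5", 1950.0))

#: thermal time of the one-week regrowth window (°C·day)
DEFAULT_GDD_WEEK = 90.0


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic top-view scene (all units noted)."""

    size: tuple[int, int] = (512, 512)          # rows, cols px
    pixels_per_cm: float = 74.36 / 4            # field optics, 4x downsampled crop
    centre: tuple[float, float] | None = None   # row, col px; None = frame centre
    leaf_count: int = 120
    leaf_length_cm: tuple[float, float] = (4.5, 1.0)   # mean, sd
    leaf_width_cm: tuple[float, float] = (0.55, 0.1)   # mean, sd
    leaf_taper: float = 0.3                     # relative width loss at the tip
    leaf_curvature: float = 0.35                # sd of total bend angle, rad
    green_hue_range: tuple[int, int] = (45, 95)        # HSV8 hue of foliage
    leaf_sat_range: tuple[int, int] = (140, 220)
    leaf_val_range: tuple[int, int] = (100, 200)
    brown_sector_fraction: float = 0.0          # fraction of leaves gone yellow-brown
    specular_highlight_rate: float = 0.001      # per-leaf-pixel highlight probability
    soil_rgb: tuple[int, int, int] = (112, 96, 80)
    soil_roughness: float = 0.5                 # luminance texture amplitude, 0..1
    moisture_gradient: float = 0.15             # relative darkening across the frame
    algae_patch_fraction: float = 0.02          # fraction of frame under algae
    weed_count: int = 3
    gain: float = 1.0                           # global illumination, nominal 0.7..1.3
    white_balance_shift: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("brown_sector_fraction", "specular_highlight_rate",
                     "algae_patch_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.leaf_count < 1:
            raise ValueError("leaf_count must be >= 1")
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass
class SyntheticScene:
    image: RasterImage
    truth: np.ndarray
    params: SceneParams
    true_area_cm2: float
    solved_scale: float = 1.0   # size factor used by the target-area solver


# ------------------------------------------------------------- rendering ----

def _multi_octave_noise(rng: np.random.Generator, shape, scales=(4, 16, 48)) -> np.ndarray:
    """Zero-mean, unit-std smooth noise as a sum of Gaussian-blurred octaves."""
    acc = np.zeros(shape, dtype=np.float64)
    for w, s in zip((1.0, 0.7, 0.5), scales):
        layer = ndimage.gaussian_filter(rng.standard_normal(shape), s)
        sd = layer.std()
        if sd > 0:
            acc += w * layer / sd
    acc -= acc.mean()
    sd = acc.std()
    return acc / sd if sd > 0 else acc


def _hsv8_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    r, g, b = colorsys.hsv_to_rgb(h / 255.0, s / 255.0, v / 255.0)
    return np.array([r, g, b]) * 255.0


_DISK_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    if radius not in _DISK_CACHE:
        r = np.arange(-radius, radius + 1)
        dr, dc = np.meshgrid(r, r, indexing="ij")
        keep = dr**2 + dc**2 <= radius**2
        _DISK_CACHE[radius] = (dr[keep], dc[keep])
    return _DISK_CACHE[radius]


def _stamp_curve(shape, start, theta, bend, length_px, half_width_px, taper=0.3):
    """Pixel coordinates of a curved tapering stroke (set of stamped disks)."""
    rows, cols = shape
    n_steps = max(3, int(length_px / 0.7))
    t = np.linspace(0.0, 1.0, n_steps)
    angles = theta + bend * t
    step = length_px / n_steps
    drow = np.cumsum(-np.sin(angles) * step)
    dcol = np.cumsum(np.cos(angles) * step)
    rr = start[0] + drow
    cc = start[1] + dcol
    radii = np.maximum(0.8, half_width_px * (1.0 - taper * t))
    out_r, out_c = [], []
    for r0, c0, rad in zip(rr, cc, radii):
        # sub-pixel circle test: keeps the rasterized area a smooth
        # function of the radius, which the area solver relies on
        dr, dc = _disk_offsets(int(np.ceil(rad)))
        pix_r = np.floor(r0) + dr
        pix_c = np.floor(c0) + dc
        keep = (pix_r - r0) ** 2 + (pix_c - c0) ** 2 <= rad**2
        out_r.append(pix_r[keep].astype(np.int64))
        out_c.append(pix_c[keep].astype(np.int64))
    pr = np.concatenate(out_r)
    pc = np.concatenate(out_c)
    keep = (pr >= 0) & (pr < rows) & (pc >= 0) & (pc < cols)
    return pr[keep], pc[keep]


def _render(params: SceneParams, length_scale: float = 1.0,
            width_scale: float = 1.0,
            count_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Render (float RGB canvas, truth mask) before lighting is applied."""
    rng = np.random.default_rng(params.seed)
    rows, cols = params.size
    ppcm = params.pixels_per_cm

    # --- soil: base colour, luminance texture, moisture gradient, chroma noise
    base = np.asarray(params.soil_rgb, dtype=np.float64)
    lum = 1.0 + 0.22 * params.soil_roughness * _multi_octave_noise(rng, (rows, cols))
    grad_dir = rng.uniform(0.0, 2.0 * np.pi)
    rg, cg = np.meshgrid(np.linspace(0, 1, rows), np.linspace(0, 1, cols), indexing="ij")
    ramp = rg * np.sin(grad_dir) + cg * np.cos(grad_dir)
    ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1e-9)
    moisture = 1.0 - params.moisture_gradient * ramp
    img = base[None, None, :] * (lum * moisture)[:, :, None]
    # chroma noise is spatially smooth, as in demosaiced/JPEG camera output
    chroma = rng.normal(0.0, 1.5, size=img.shape)
    for ch in range(3):
        chroma[:, :, ch] = ndimage.gaussian_filter(chroma[:, :, ch], 1.2) * 3.0
    img += chroma

    # plant centre and nominal tuft radius, needed for algae placement
    centre = params.centre
    if centre is None:
        centre = (rows / 2.0, cols / 2.0)
    centre = np.asarray(centre, dtype=np.float64) + rng.normal(0.0, 1.5, size=2)
    len_mu, len_sd = params.leaf_length_cm
    tuft_radius = (len_mu + 2.0 * len_sd + 0.5) * ppcm * length_scale

    # --- algae: green-hued patches with fine texture, background in truth.
    # Patches sit on open moist soil away from the weeded tuft footprint,
    # so they never merge with the plant object.
    frame_area = rows * cols
    patch_r_px = max(3.0, 2.5 * ppcm)
    n_patches = int(round(params.algae_patch_fraction * frame_area / (np.pi * patch_r_px**2)))
    for _ in range(n_patches):
        ry = patch_r_px * rng.uniform(0.6, 1.4)
        rx = patch_r_px * rng.uniform(0.6, 1.4)
        cy = cx = None
        for _attempt in range(30):
            py, px = rng.uniform(0, rows), rng.uniform(0, cols)
            if np.hypot(py - centre[0], px - centre[1]) > tuft_radius + max(ry, rx):
                cy, cx = py, px
                break
        if cy is None:
            continue
        yy, xx = np.ogrid[:rows, :cols]
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        h = rng.uniform(50, 85)
        s = rng.uniform(90, 150)
        v = rng.uniform(70, 120)
        colour = _hsv8_to_rgb(h, s, v)
        # fine texture scale (1-2 px) distinguishes algae from foliage
        tex = 1.0 + 0.35 * ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 1.0)
        img[inside] = colour[None, :] * tex[inside, None]

    # --- weeds: small green speckles, likewise outside the weeded zone
    for _ in range(params.weed_count):
        wy = wx = None
        for _attempt in range(30):
            py, px = rng.uniform(0, rows), rng.uniform(0, cols)
            if np.hypot(py - centre[0], px - centre[1]) > tuft_radius + 4:
                wy, wx = py, px
                break
        if wy is None:
            continue
        wr = int(rng.integers(1, 4))
        dr, dc = _disk_offsets(wr)
        pr = np.round(wy + dr).astype(np.int64)
        pc = np.round(wx + dc).astype(np.int64)
        keep = (pr >= 0) & (pr < rows) & (pc >= 0) & (pc < cols)
        colour = _hsv8_to_rgb(rng.uniform(45, 95), rng.uniform(120, 200), rng.uniform(90, 170))
        img[pr[keep], pc[keep]] = colour

    # --- plant: curved tapering leaves radiating from the centre
    truth = np.zeros((rows, cols), dtype=bool)
    sector_start = rng.uniform(0.0, 2.0 * np.pi)
    sector_width = 2.0 * np.pi * params.brown_sector_fraction
    wid_mu, wid_sd = params.leaf_width_cm
    n_leaves = max(1, round(params.leaf_count * count_scale))
    for _ in range(n_leaves):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        length = max(0.8, rng.normal(len_mu, len_sd)) * ppcm * length_scale
        width = max(0.15, rng.normal(wid_mu, wid_sd)) * ppcm * width_scale
        bend = rng.normal(0.0, params.leaf_curvature)
        start = centre + rng.normal(0.0, 0.4 * ppcm, size=2)
        pr, pc = _stamp_curve(
            (rows, cols), start, theta, bend, length, width / 2.0, params.leaf_taper
        )
        if pr.size == 0:
            continue
        in_brown = (theta - sector_start) % (2.0 * np.pi) < sector_width
        if in_brown:
            h = rng.uniform(16, 26)
            s = rng.uniform(110, 170)
            v = rng.uniform(120, 190)
        else:
            h = rng.uniform(*params.green_hue_range)
            s = rng.uniform(*params.leaf_sat_range)
            v = rng.uniform(*params.leaf_val_range)
        colour = _hsv8_to_rgb(h, s, v)
        shade = 1.0 + 0.06 * rng.standard_normal(pr.size)
        # continuous per-pixel colour variation (leaf shading, specular angle)
        grain = rng.normal(0.0, 4.0, size=(pr.size, 3))
        img[pr, pc] = colour[None, :] * shade[:, None] + grain
        truth[pr, pc] = True

    # --- specular highlights on the foliage
    if params.specular_highlight_rate > 0 and truth.any():
        pr, pc = np.nonzero(truth)
        n_hl = rng.binomial(pr.size, params.specular_highlight_rate)
        if n_hl > 0:
            pick = rng.choice(pr.size, size=n_hl, replace=False)
            img[pr[pick], pc[pick]] = (245.0, 245.0, 235.0)

    return img, truth


def _apply_lighting(img: np.ndarray, params: SceneParams) -> np.ndarray:
    wb = np.asarray(params.white_balance_shift, dtype=np.float64)
    out = np.clip(img * params.gain * wb[None, None, :], 0.0, 255.0)
    return np.floor(out + 0.5).astype(np.uint8)


def generate_scene(params: SceneParams | None = None, **overrides) -> SyntheticScene:
    """Render one scene; deterministic for fixed parameters (incl. seed)."""
    if params is None:
        params = SceneParams(**overrides)
    elif overrides:
        params = dataclasses.replace(params, **overrides)
    img, truth = _render(params)
    rgb = RasterImage(_apply_lighting(img, params), "RGB8")
    area = float(truth.sum() / params.pixels_per_cm**2)
    return SyntheticScene(rgb, truth, params, area)


def scene_for_area(
    params: SceneParams,
    target_cm2: float,
    tol: float = 0.05,
    max_iter: int = 12,
    initial_scale: float = 1.0,
) -> SyntheticScene:
    """Render a scene whose true leaf area hits a target within ``tol``.

    Plant size is driven mostly by tiller count (as in real plants, where a
    larger plant is a denser tuft rather than one with longer leaves): the
    solved factor s scales the leaf count by s^0.8 and the leaf dimensions
    by s^0.6.  Raises when the target cannot fit in the frame.
    """
    if target_cm2 <= 0:
        raise ValueError("target area must be positive")
    ppcm = params.pixels_per_cm
    target_px = target_cm2 * ppcm**2
    rows, cols = params.size
    if target_px > 0.5 * rows * cols:
        raise ValueError("target area infeasible for the frame")
    scale = max(0.05, initial_scale)
    img = truth = None
    rel = np.inf
    for _ in range(max_iter):
        dim = scale**0.6
        img, truth = _render(
            params, length_scale=dim, width_scale=dim, count_scale=scale**0.8
        )
        area_px = truth.sum()
        if area_px == 0:
            scale *= 2.0
            continue
        rel = area_px / target_px
        if abs(rel - 1.0) <= tol:
            break
        # area responds roughly quadratically to the solved factor
        scale *= rel ** (-0.55)
        if scale > 12.0:
            raise ValueError("target area infeasible for the frame")
    if truth is None or abs(rel - 1.0) > tol:
        raise ValueError(
            f"could not reach target area {target_cm2:.1f} cm^2 within {tol:.0%}"
        )
    rgb = RasterImage(_apply_lighting(img, params), "RGB8")
    area = float(truth.sum() / ppcm**2)
    return SyntheticScene(rgb, truth, params, area, solved_scale=scale)


# ---------------------------------------------------------- growth series ----

def generate_growth_series(
    expansion_slope: float = 0.059,     # cm^2 per degree-day (lateral expansion)
    regrowth_rate: float = 0.2,         # cm^2 per degree-day (one-week regrowth)
    noise_sd: float = 0.0,              # cm^2, Gaussian noise on the W0 targets
    base_area_cm2: float = 40.0,        # base area at the first cut
    cuts=DEFAULT_CUTS,
    gdd_week: float = DEFAULT_GDD_WEEK,
    weeks: tuple[str, ...] = ("W0", "W1"),
    genotype_id: str = "G001",
    replicate: int = 1,
    min_area_cm2: float = 5.0,
    scene_params: SceneParams | None = None,
    seed: int = 0,
    render: bool = True,
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Scenes plus the expected observation table for one simulated plant.

    W0 target areas follow ``base + slope x gdd`` with optional Gaussian
    noise (floored at ``min_area_cm2``); W1 targets add
    ``regrowth_rate x gdd_week``.  Scenes are rendered with leaf dimensions
    solved to hit each target within 5 % (``render=False`` skips rendering
    and returns only the table).
    """
    gdds = [g for _, g in cuts]
    if any(b <= a for a, b in zip(gdds, gdds[1:])):
        raise ValueError("cut thermal times must be strictly increasing")
    rng = np.random.default_rng(seed)
    base_params = scene_params or SceneParams()
    scenes: list[SyntheticScene] = []
    records = []
    warm_scale, warm_target = 1.0, None
    for label, gdd in cuts:
        w0 = base_area_cm2 + expansion_slope * gdd + rng.normal(0.0, noise_sd)
        w0 = max(min_area_cm2, w0)
        targets = {"W0": (w0, gdd), "W1": (w0 + regrowth_rate * gdd_week, gdd + gdd_week)}
        for week in weeks:
            target, gdd_obs = targets[week]
            scene_seed = int(rng.integers(0, 2**31 - 1))
            true_area = np.nan
            if render:
                p = dataclasses.replace(base_params, seed=scene_seed)
                guess = 1.0
                if warm_target is not None:
                    guess = warm_scale * (target / warm_target) ** 0.55
                scene = scene_for_area(p, target, initial_scale=guess)
                warm_scale, warm_target = scene.solved_scale, target
                scenes.append(scene)
                true_area = scene.true_area_cm2
            records.append(
                {
                    "genotype_id": genotype_id,
                    "replicate": replicate,
                    "timepoint": label,
                    "week": week,
                    "gdd": gdd_obs,
                    "area_cm2": target,
                    "true_area_cm2": true_area,
                    "seed": scene_seed,
                }
            )
    return scenes, pd.DataFrame(records)


def generate_temperature_series(
    n_days: int,
    mean_temp: float = 12.0,            # °C, season mean
    seasonal_amplitude: float = 8.0,    # °C, sinusoidal annual swing
    diurnal_range: float = 8.0,         # °C between tmin and tmax
    noise_sd: float = 2.0,              # °C, day-to-day weather noise
    start: str = "2014-04-01",
    seed: int = 0,
):
    """Daily min/max temperature records: seasonal sinusoid plus noise."""
    from .traits import TemperatureDay

    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy()
    daily_mean = (
        mean_temp
        + seasonal_amplitude * np.sin(2.0 * np.pi * (doy - 105) / 365.25)
        + rng.normal(0.0, noise_sd, size=n_days)
    )
    half = diurnal_range / 2.0
    jit_lo = np.abs(rng.normal(0.0, noise_sd / 2.0, size=n_days))
    jit_hi = np.abs(rng.normal(0.0, noise_sd / 2.0, size=n_days))
    tmin = daily_mean - half - jit_lo
    tmax = daily_mean + half + jit_hi
    # the daily mean of the pair must stay on the profile
    shift = daily_mean - (tmin + tmax) / 2.0
    tmin += shift
    tmax += shift
    return [
        TemperatureDay(date=d.date(), tmin=float(lo), tmax=float(hi))
        for d, lo, hi in zip(dates, tmin, tmax)
    ]
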