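"""Pixel-level processing of polarization-resolved fluorescence images.

Covers de-interleaving of mixed-polarization frames (polarization alternated
between adjacent pixel columns or rows during acquisition), calibration
corrections (background, bleed-through, illumination gain, bleaching),
per-pixel dichroic-ratio and azimuth maps, and the hue/brightness
renderings used to visualize linear dichroism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.colors import hsv_to_rgb

log = logging.getLogger(__name__)

__all__ = [
    "MixedPolarizationImage",
    "Calibration",
    "PolarizationPair",
    "PolarizationStack",
    "PixelLDMap",
    "deinterleave",
    "correct_pair",
    "dichroic_ratio_map",
    "fit_stack_per_pixel",
    "correct_bleaching",
    "render_ld_image",
    "render_azimuth_overlay",
    "make_ld_colorbar",
    "make_azimuth_colorwheel",
]

SCHEMES = ("per_pixel_column", "per_pixel_row", "per_row")
PHASES = ("h_first", "v_first")

#: default hue ramp for LD renderings, in log2(r) units
DEFAULT_HUE_RANGE = (-2.0, 2.0)


@dataclass(frozen=True)
class MixedPolarizationImage:
    """Single frame in which excitation polarization alternates per pixel.

    ``scheme`` names the modulation pattern: ``per_pixel_column`` alternates
    between adjacent columns (modulation along x, the scan direction);
    ``per_pixel_row``/``per_row`` alternate between adjacent rows.  ``phase``
    states which polarization was acquired first (at column/row 0).
    """

    pixels: np.ndarray
    scheme: str = "per_pixel_column"
    phase: str = "h_first"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("mixed image must be 2-D")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("intensities must be finite and >= 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        axis = self.modulation_axis
        if px.shape[axis] % 2:
            raise ValueError(
                f"extent along modulation axis {axis} must be even, got {px.shape[axis]}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def modulation_axis(self) -> int:
        return 1 if self.scheme == "per_pixel_column" else 0


@dataclass(frozen=True)
class Calibration:
    """Per-pair calibration: channel backgrounds, bleed-through fraction k,
    illumination gain g applied to the vertical channel."""

    background_h: float | None = None
    background_v: float | None = None
    bleed_k: float = 0.0
    gain_g: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.bleed_k < 1.0:
            raise ValueError(f"bleed_k must be in [0, 1), got {self.bleed_k}")
        if self.gain_g <= 0:
            raise ValueError(f"gain_g must be positive, got {self.gain_g}")


@dataclass(frozen=True)
class PolarizationPair:
    """Co-registered horizontal/vertical-excitation intensity images."""

    f_h: np.ndarray
    f_v: np.ndarray
    modality: str = "1p"
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self):
        fh = np.asarray(self.f_h, dtype=float)
        fv = np.asarray(self.f_v, dtype=float)
        if fh.shape != fv.shape:
            raise ValueError(f"channel shapes differ: {fh.shape} vs {fv.shape}")
        object.__setattr__(self, "f_h", fh)
        object.__setattr__(self, "f_v", fv)
        object.__setattr__(self, "modality", str(self.modality).lower())


@dataclass(frozen=True)
class PolarizationStack:
    """Frames acquired at uniformly incremented excitation polarizations."""

    frames: np.ndarray  # (n_frames, H, W)
    angles: np.ndarray  # degrees
    modality: str = "1p"

    def __post_init__(self):
        fr = np.asarray(self.frames, dtype=float)
        ang = np.asarray(self.angles, dtype=float)
        if fr.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if fr.shape[0] != ang.size:
            raise ValueError("one angle per frame required")
        if ang.size < 4:
            raise ValueError("at least 4 frames/polarizations required")
        if not np.all(np.diff(ang) > 0):
            raise ValueError("angles must be strictly increasing")
        steps = np.diff(ang)
        if not np.allclose(steps, steps[0], atol=1e-6):
            log.warning("nonuniform polarization steps; per-pixel fit falls back to least squares")
        span = (ang.max() - ang.min()) % 360.0
        if min(span, 180.0) < 165.0 and ang.size * steps[0] < 165.0:
            raise ValueError("angles must span >= 165 degrees of unique polarizations")
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "angles", ang)
        object.__setattr__(self, "modality", str(self.modality).lower())

    @property
    def uniform(self) -> bool:
        steps = np.diff(self.angles)
        return bool(np.allclose(steps, steps[0], atol=1e-6))


@dataclass
class PixelLDMap:
    """Per-pixel LD result: intensity, dichroic ratio (r or r_max), azimuth.

    ``ld`` is r = F_h/F_v in pair mode, r_max = (A+B)/A in stack mode;
    ``azimuth`` (stack mode only) is the polarization direction of maximal
    fluorescence in degrees mod 180, NaN where undefined.
    """

    intensity: np.ndarray
    ld: np.ndarray
    valid: np.ndarray
    azimuth: np.ndarray | None = None
    fit_a: np.ndarray | None = None  # per-pixel cos^2 fit offset A
    fit_b: np.ndarray | None = None  # amplitude B
    fit_c: np.ndarray | None = None  # phase C (deg)
    mode: str = "pair"

    def log2_ld(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.valid & (self.ld > 0), np.log2(np.maximum(self.ld, 1e-300)), np.nan)


def deinterleave(mixed: MixedPolarizationImage, modality: str = "1p",
                 calibration: Calibration | None = None) -> PolarizationPair:
    """Split a mixed-polarization frame into a co-registered channel pair.

    Each channel keeps its measured values on its own sub-grid and is
    re-gridded to the full pixel grid by linear interpolation along the
    modulation axis (edge pixels extend the nearest measured value), so the
    two returned images are co-registered at every pixel.
    """
    px = mixed.pixels
    axis = mixed.modulation_axis
    work = px if axis == 1 else px.T
    n_rows, n_cols = work.shape
    cols = np.arange(n_cols)
    even, odd = cols[0::2], cols[1::2]

    def regrid(sub_cols: np.ndarray) -> np.ndarray:
        out = np.empty_like(work)
        for i in range(n_rows):
            out[i] = np.interp(cols, sub_cols, work[i, sub_cols])
        return out

    first, second = regrid(even), regrid(odd)
    if mixed.phase == "h_first":
        fh, fv = first, second
    else:
        fh, fv = second, first
    if axis == 0:
        fh, fv = fh.T, fv.T
    return PolarizationPair(f_h=fh, f_v=fv, modality=modality,
                            calibration=calibration or Calibration())


def correct_pair(pair: PolarizationPair) -> PolarizationPair:
    """Background subtraction, linear bleed-through unmixing, gain balancing.

    Background defaults to the 1st percentile of each channel when not
    supplied (unattended batch processing).  Bleed-through is removed by
    linear unmixing f_h' = (f_h − k·f_v)/(1 − k²), f_v' = (f_v − k·f_h)/(1 − k²);
    the vertical channel is then multiplied by the illumination gain g.
    """
    cal = pair.calibration
    k, g = cal.bleed_k, cal.gain_g
    if k >= 1.0:
        raise ValueError("bleed_k must be < 1")
    bg_h = np.percentile(pair.f_h, 1.0) if cal.background_h is None else cal.background_h
    bg_v = np.percentile(pair.f_v, 1.0) if cal.background_v is None else cal.background_v
    fh = np.clip(pair.f_h - bg_h, 0.0, None)
    fv = np.clip(pair.f_v - bg_v, 0.0, None)
    if k > 0:
        det = 1.0 - k * k
        fh2 = (fh - k * fv) / det
        fv2 = (fv - k * fh) / det
        fh, fv = fh2, fv2
    fv = fv * g
    return replace(pair, f_h=fh, f_v=fv,
                   calibration=Calibration(background_h=0.0, background_v=0.0))


def dichroic_ratio_map(pair: PolarizationPair, min_intensity: float = 0.0) -> PixelLDMap:
    """Per-pixel dichroic ratio r = F_h/F_v of a corrected pair.

    Pixels where either channel falls below ``min_intensity`` (or F_v is
    nonpositive) are masked invalid rather than erroring.
    """
    fh, fv = pair.f_h, pair.f_v
    thr = max(min_intensity, 0.0)
    valid = (fh >= thr) & (fv >= thr) & (fv > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ld = np.where(valid, fh / np.where(fv > 0, fv, 1.0), np.nan)
    return PixelLDMap(intensity=fh + fv, ld=ld, valid=valid, mode="pair")


def fit_stack_per_pixel(stack: PolarizationStack, min_intensity: float = 0.0) -> PixelLDMap:
    """Per-pixel fit of F = A + B cos²(θ − C) across a polarization stack.

    For uniformly spaced angles covering the half-circle this is solved in
    closed form by harmonic regression on the 2θ Fourier component (exact on
    noiseless data from the model); nonuniform spacing falls back to linear
    least squares on the (1, cos2θ, sin2θ) basis.  Returns r_max = (A+B)/A
    and the molecular azimuth C.
    """
    F = stack.frames
    th = np.radians(stack.angles)
    n = th.size
    if stack.uniform:
        a0 = F.mean(axis=0)
        a2 = (2.0 / n) * np.tensordot(np.cos(2 * th), F, axes=(0, 0))
        b2 = (2.0 / n) * np.tensordot(np.sin(2 * th), F, axes=(0, 0))
    else:
        log.info("nonuniform angles: least-squares per-pixel cos^2 fit")
        X = np.stack([np.ones_like(th), np.cos(2 * th), np.sin(2 * th)], axis=1)
        coef, *_ = np.linalg.lstsq(X, F.reshape(n, -1), rcond=None)
        a0 = coef[0].reshape(F.shape[1:])
        a2 = coef[1].reshape(F.shape[1:])
        b2 = coef[2].reshape(F.shape[1:])
    m = np.hypot(a2, b2)
    valid = (a0 >= min_intensity) & (a0 > m)
    with np.errstate(divide="ignore", invalid="ignore"):
        rmax = np.where(valid, (a0 + m) / np.where(a0 > m, a0 - m, 1.0), np.nan)
    azim = np.degrees(0.5 * np.arctan2(b2, a2)) % 180.0
    azim = np.where(valid & (m > 1e-12 * np.maximum(a0, 1e-300)), azim, np.nan)
    # cos^2 parametrization: F = A + B cos^2(th - C) with A = a0 - m, B = 2 m
    return PixelLDMap(
        intensity=a0 * n,
        ld=rmax,
        valid=valid,
        azimuth=azim,
        fit_a=a0 - m,
        fit_b=2 * m,
        fit_c=azim,
        mode="stack",
    )


def correct_bleaching(stack: PolarizationStack, mask: np.ndarray | None = None) -> PolarizationStack:
    """Remove a single-exponential bleaching trend from a stack.

    Fits frame means (over ``mask`` if given) to M·exp(−λ·i) by log-linear
    regression and divides frame i by exp(−λ·i), so the detrended frame means
    share a common level.
    """
    F = stack.frames
    if mask is not None:
        means = np.array([f[mask].mean() for f in F])
    else:
        means = F.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise ValueError("nonpositive frame means; cannot fit bleaching trend")
    i = np.arange(means.size, dtype=float)
    slope, _ = np.polyfit(i, np.log(means), 1)
    lam = -slope
    corr = np.exp(-lam * i)
    fixed = F / corr[:, None, None]
    return replace(stack, frames=fixed)


def _brightness(intensity: np.ndarray, valid: np.ndarray) -> np.ndarray:
    vals = intensity[valid & np.isfinite(intensity)]
    p99 = np.percentile(vals, 99.0) if vals.size else 1.0
    p99 = p99 if p99 > 0 else 1.0
    return np.clip(intensity / p99, 0.0, 1.0)


def render_ld_image(
    ldmap: PixelLDMap,
    hue_range: tuple[float, float] = DEFAULT_HUE_RANGE,
    mode: str = "ld_hue",
) -> np.ndarray:
    """Render LD (or azimuth) as hue and intensity as brightness, uint8 RGB.

    ``ld_hue``: clipped log₂(ld) maps linearly over a blue→red ramp between
    ``hue_range``.  ``azimuth_hue``: azimuth maps onto the cyclic HSV wheel;
    valid pixels without a defined azimuth stay gray.  Invalid pixels are
    black.  Pure function of its inputs.
    """
    lo, hi = hue_range
    if lo >= hi:
        raise ValueError("hue_range lo must be < hi")
    v = _brightness(ldmap.intensity, ldmap.valid)
    h = np.zeros_like(v)
    s = np.ones_like(v)
    if mode == "ld_hue":
        x = np.clip((ldmap.log2_ld() - lo) / (hi - lo), 0.0, 1.0)
        x = np.where(np.isfinite(x), x, 0.5)
        h = (1.0 - x) * (2.0 / 3.0)  # blue (2/3) -> red (0)
    elif mode == "azimuth_hue":
        if ldmap.azimuth is None:
            raise ValueError("azimuth_hue requires a stack-mode map with azimuths")
        az_ok = np.isfinite(ldmap.azimuth)
        h = np.where(az_ok, np.where(az_ok, ldmap.azimuth, 0.0) / 180.0, 0.0)
        s = np.where(az_ok, 1.0, 0.0)
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    v = np.where(ldmap.valid, v, 0.0)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    return (np.round(rgb * 255)).astype(np.uint8)


def make_ld_colorbar(hue_range: tuple[float, float] = DEFAULT_HUE_RANGE,
                     width: int = 256, height: int = 24) -> np.ndarray:
    """Reference color bar using exactly the hue ramp of ``render_ld_image``."""
    lo, hi = hue_range
    if lo >= hi:
        raise ValueError("hue_range lo must be < hi")
    x = np.linspace(0.0, 1.0, width)
    h = (1.0 - x) * (2.0 / 3.0)
    hsv = np.stack([h, np.ones_like(h), np.ones_like(h)], axis=-1)
    row = (np.round(hsv_to_rgb(hsv) * 255)).astype(np.uint8)
    return np.tile(row[None, :, :], (height, 1, 1))


def make_azimuth_colorwheel(size: int = 129) -> np.ndarray:
    """Color wheel mapping direction (mod 180 deg) to the azimuth hue."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - c, yy - c
    ang = np.degrees(np.arctan2(-dy, dx)) % 180.0
    rad = np.hypot(dx, dy) / c
    h = ang / 180.0
    v = (rad <= 1.0).astype(float)
    hsv = np.stack([h, np.ones_like(h), v], axis=-1)
    return (np.round(hsv_to_rgb(hsv) * 255)).astype(np.uint8)


def render_azimuth_overlay(
    ldmap: PixelLDMap,
    spacing: int = 8,
    length: float | str = 6.0,
    color_mode: str = "azimuth",
    color: tuple[int, int, int] = (0, 255, 0),
) -> np.ndarray:
    """Overlay azimuth line segments on a brightness image, uint8 RGB.

    Segments are centered on an evenly spaced grid of valid pixels, oriented
    at the local azimuth.  ``length`` may be a pixel count or ``"rmax"``
    (length proportional to log₂ r_max).  ``color_mode`` is ``"azimuth"``
    (hue from the azimuth wheel, scaled by local brightness) or ``"fixed"``.
    With spacing 1 and length 1 the azimuth color mode degenerates to the
    per-pixel azimuth-hue rendering.
    """
    from skimage.draw import line as draw_line

    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if ldmap.azimuth is None:
        raise ValueError("overlay requires a stack-mode map with azimuths")
    v = np.where(ldmap.valid, _brightness(ldmap.intensity, ldmap.valid), 0.0)
    base = (np.round(np.stack([v, v, v], axis=-1) * 255)).astype(np.uint8)
    H, W = v.shape
    half = max(int(spacing) // 2, 0)
    for yy in range(half, H, int(spacing)):
        for xx in range(half, W, int(spacing)):
            az = ldmap.azimuth[yy, xx]
            if not (ldmap.valid[yy, xx] and np.isfinite(az)):
                continue
            if length == "rmax":
                l2 = np.log2(ldmap.ld[yy, xx]) if ldmap.ld[yy, xx] > 0 else 0.0
                L = float(np.clip(l2, 0.0, 4.0)) / 4.0 * 2.0 * spacing
            else:
                L = float(length)
            if color_mode == "azimuth":
                rgb = hsv_to_rgb([az / 180.0, 1.0, v[yy, xx]])
                col = tuple(int(round(c * 255)) for c in rgb)
            else:
                col = color
            if L <= 1.0:
                base[yy, xx] = col
                continue
            # display-CCW angle with y down: dy = -sin
            dx = 0.5 * L * np.cos(np.radians(az))
            dy = -0.5 * L * np.sin(np.radians(az))
            r0, c0 = int(round(yy - dy)), int(round(xx - dx))
            r1, c1 = int(round(yy + dy)), int(round(xx + dx))
            rr, cc = draw_line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            base[rr[keep], cc[keep]] = col
    return base
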