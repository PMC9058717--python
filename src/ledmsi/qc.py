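"""Lighting and imaging quality-control procedures.

Four checks qualify the dome before an experiment, mirroring the protocol a
careful user runs on the physical device:

1. dark-frame subtraction (built into every capture, see ``acquisition``);
2. illumination evenness, quantified as mean gray value (MGV) and SD inside
   a growing circular region of interest (:func:`radial_profile`);
3. sensor band sensitivity on a certified reflectance standard, with
   automatic duty reduction of saturating bands (:func:`band_sensitivity`,
   :func:`adjust_intensity`);
4. temporal consistency of repeated captures (:func:`consistency_stats`).

:func:`estimate_fwhm` measures a spectral peak's full width at half
maximum, used to verify LED channel band widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acquisition import DeviceBackend, capture_band, _spawn_seeds
from .bands import SpectralBand
from .errors import CalibrationError
from .images import BandImage

#: Acceptance bound used in QC reports: relative SD of the ROI MGV across a
#: temporal consistency run should stay below this percentage.
CONSISTENCY_SD_PCT_BOUND = 0.5

#: Saturating bands are reduced until the ROI MGV falls below this target.
DEFAULT_TARGET_MGV = 240.0

#: Safety factor applied to the target when rescaling the duty cycle.
ADJUST_SAFETY = 0.98


def _is_saturated(raw, roi: "CircularROI") -> bool:
    # Saturated when the lit-frame ROI MGV rounds to full scale: with noise
    # a clipped band leaves a few pixels just under 255, so strict equality
    # would miss genuinely saturated channels.
    return roi_mgv(raw, roi) >= 254.5


@dataclass
class CircularROI:
    """A circular region of interest: centre (x, y) and radius, in pixels."""

    center_px: tuple[float, float]
    radius_px: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape[:2]
        xx, yy = np.meshgrid(np.arange(w), np.arange(h))
        cx, cy = self.center_px
        return ((xx - cx) ** 2 + (yy - cy) ** 2) <= self.radius_px ** 2


def _pixels(image: BandImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, BandImage) else np.asarray(image)


def roi_mgv(image: BandImage | np.ndarray, roi: CircularROI) -> float:
    """Mean gray value over pixels whose centres fall inside the ROI."""
    px = _pixels(image)
    mask = roi.mask(px.shape[:2])
    if not mask.any():
        raise ValueError("ROI contains no pixel centres")
    if px.ndim == 3:
        px = px.mean(axis=-1)
    return float(px[mask].mean())


@dataclass
class RadialProfile:
    """MGV and SD inside cumulative circles of growing radius."""

    radii_mm: np.ndarray
    mgv: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if not (len(self.radii_mm) == len(self.mgv) == len(self.sd)):
            raise ValueError("radii, mgv and sd must have equal length")
        if np.any(np.diff(self.radii_mm) <= 0):
            raise ValueError("radii must be strictly increasing")


def radial_profile(image: BandImage | np.ndarray,
                   center_px: tuple[float, float],
                   step_mm: float = 0.1, max_radius_mm: float = 70.0,
                   pixel_pitch_mm: float = 0.25) -> RadialProfile:
    """MGV/SD profile inside a growing circle around ``center_px``.

    For each radius r in {step, 2*step, ..., max}, the statistics are taken
    over all pixels whose centres lie within distance r of the centre —
    cumulative circles, not annuli.  SDs are sample SDs (ddof=1; zero for a
    single pixel); circles containing no pixel centre yield NaN.
    """
    px = _pixels(image).astype(float)
    if px.ndim != 2:
        raise ValueError("radial_profile expects a 2-D grayscale image")
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel_pitch_mm must be > 0")
    if max_radius_mm < pixel_pitch_mm:
        raise ValueError("max_radius_mm smaller than one pixel")
    h, w = px.shape
    cx, cy = center_px
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("center must lie inside the image")

    xx, yy = np.meshgrid(np.arange(w), np.arange(h))
    dist_mm = np.hypot(xx - cx, yy - cy).ravel() * pixel_pitch_mm
    order = np.argsort(dist_mm, kind="stable")
    dist_sorted = dist_mm[order]
    vals_sorted = px.ravel()[order]
    csum = np.concatenate(([0.0], np.cumsum(vals_sorted)))
    csum2 = np.concatenate(([0.0], np.cumsum(vals_sorted ** 2)))

    radii = np.arange(step_mm, max_radius_mm + step_mm / 2.0, step_mm)
    counts = np.searchsorted(dist_sorted, radii, side="right")
    mgv = np.full(radii.shape, np.nan)
    sd = np.full(radii.shape, np.nan)
    nz = counts > 0
    mgv[nz] = csum[counts[nz]] / counts[nz]
    one = counts == 1
    sd[one] = 0.0
    many = counts > 1
    n = counts[many].astype(float)
    ss = csum2[counts[many]] - n * mgv[many] ** 2
    sd[many] = np.sqrt(np.maximum(ss, 0.0) / (n - 1.0))
    return RadialProfile(radii, mgv, sd)


@dataclass
class ConsistencyStats:
    """Temporal stability of the ROI MGV across a frame sequence."""

    n_frames: int
    mean_mgv: float
    sd_mgv: float

    @property
    def sd_pct(self) -> float:
        return 100.0 * self.sd_mgv / self.mean_mgv

    @property
    def within_bound(self) -> bool:
        return self.sd_pct < CONSISTENCY_SD_PCT_BOUND


def consistency_stats(frames, roi: CircularROI) -> ConsistencyStats:
    """Per-frame ROI MGV, then mean and sample SD (ddof=1) across frames."""
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    shapes = {_pixels(f).shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("frames must share one shape")
    mgvs = np.array([roi_mgv(f, roi) for f in frames])
    mean = float(mgvs.mean())
    if mean == 0:
        raise ValueError("mean MGV is zero; relative SD undefined")
    return ConsistencyStats(len(frames), mean, float(mgvs.std(ddof=1)))


@dataclass
class SensitivityEntry:
    band_name: str
    peak_nm: float
    mgv: float
    saturated: bool
    final_duty: float


@dataclass
class SensitivityCurve:
    """Per-band ROI MGV on the reflectance standard: the system's effective
    spectral response."""

    entries: list[SensitivityEntry] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [vars(e) for e in self.entries]


def band_sensitivity(device: DeviceBackend, bands: list[SpectralBand],
                     roi: CircularROI, seed: int = 0) -> SensitivityCurve:
    """Measure per-band dark-subtracted ROI MGV on the loaded CRS fixture.

    A band is flagged saturated when its illuminated raw frame reads full
    scale (255) across the ROI before dark subtraction.
    """
    if not bands:
        raise ValueError("band list is empty")
    curve = SensitivityCurve()
    seeds = _spawn_seeds(seed, 2 * len(bands))
    for i, band in enumerate(bands):
        device.set_band(band)
        raw = device.grab_frame(seeds[2 * i])
        saturated = _is_saturated(raw, roi)
        img = capture_band(device, band, seeds[2 * i + 1])
        curve.entries.append(SensitivityEntry(
            band.name, band.peak_nm, roi_mgv(img, roi), saturated, band.duty))
    return curve


@dataclass
class AdjustResult:
    duty: float
    mgv: float
    iterations: int
    history: list[tuple[float, float]]  # (duty, measured MGV) per iteration


def adjust_intensity(device: DeviceBackend, band: SpectralBand,
                     roi: CircularROI, target_mgv: float = DEFAULT_TARGET_MGV,
                     max_iter: int = 8, seed: int = 0) -> AdjustResult:
    """Reduce a band's duty cycle until its ROI MGV falls below the target.

    Each iteration measures the dark-subtracted ROI MGV (a saturated frame
    is read as 255) and rescales the duty by ``0.98 * target / measured``.
    The duty never rises above its starting value.  Raises
    :class:`CalibrationError` if the target is not reached in ``max_iter``
    measurements.
    """
    if not (0.0 < target_mgv < 255.0):
        raise ValueError("target_mgv must be in (0, 255)")
    duty = band.duty
    seeds = _spawn_seeds(seed, 2 * max_iter)
    history: list[tuple[float, float]] = []
    measured = math.inf
    for i in range(max_iter):
        current = band.with_duty(duty)
        device.set_band(current)
        raw = device.grab_frame(seeds[2 * i])
        img = capture_band(device, current, seeds[2 * i + 1])
        mgv_sub = roi_mgv(img, roi)
        measured = 255.0 if _is_saturated(raw, roi) else mgv_sub
        history.append((duty, measured))
        if measured < target_mgv:
            return AdjustResult(duty, mgv_sub, i + 1, history)
        duty = min(duty, duty * ADJUST_SAFETY * target_mgv / measured)
    raise CalibrationError(
        f"intensity adjustment did not reach MGV < {target_mgv} "
        f"in {max_iter} iterations (last MGV {measured:.1f})",
        duty=duty, mgv=measured, iterations=max_iter)


def estimate_fwhm(wavelength_nm: np.ndarray, intensity: np.ndarray) -> float:
    """Full width at half maximum of a sampled single-peak spectrum.

    The two half-maximum crossings flanking the global maximum are located
    by linear interpolation between adjacent samples.  Raises ValueError if
    the peak is truncated (no crossing on one side) or non-positive.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if wl.shape != y.shape or wl.ndim != 1 or wl.size < 3:
        raise ValueError("need matching 1-D arrays with at least 3 samples")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    peak = int(np.argmax(y))
    ymax = y[peak]
    if ymax <= 0:
        raise ValueError("spectrum maximum must be positive")
    half = ymax / 2.0

    def crossing(idx_range, side: str) -> float:
        for i in idx_range:
            y0, y1 = y[i], y[i + 1]
            lo, hi = (y0, y1) if side == "left" else (y1, y0)
            if lo < half <= hi:
                return wl[i] + (half - y0) / (y1 - y0) * (wl[i + 1] - wl[i])
        raise ValueError(f"no half-maximum crossing on the {side} side "
                         "(truncated peak)")

    left = crossing(range(peak - 1, -1, -1), "left")
    right = crossing(range(peak, wl.size - 1), "right")
    return float(right - left)
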