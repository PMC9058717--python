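"""Digital twin of the LED dome and camera.

The physical device is a diffusely reflective semisphere (radius R) with up
to three LED pads on a ring of radius d around a circular region of
photography (ROP, radius r), imaged from above by an 8-bit webcam.  This
module provides the forward model that turns a scene's per-pixel reflectance
spectra into the 8-bit frames the camera would record:

    signal(x, y) = gain * E(x, y) * integral[ emission(l) * R(x, y, l) * S(l) dl ]
                   + dark_offset

with E the relative irradiance field (mean 1 over the ROP), emission the
duty-scaled LED spectrum, R the scene reflectance and S the sensor's
relative spectral sensitivity.  Gaussian read noise, a Gaussian shot-noise
approximation with variance proportional to the photon signal, and a small
common-mode frame-to-frame illumination jitter are added before
round-half-to-even quantization and clipping to [0, 255].

The irradiance field mixes a uniform dome-diffused term with per-LED
inverse-square direct terms; increasing the LED count 1 -> 3 flattens the
field without changing its ROP mean, matching the behaviour of the physical
ring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import GRID, SpectralBand, led_emission_spectrum, white_led_spectrum
from .images import WHT, BandImage
from .scenes import Scene

#: Default mixing weight of the uniform dome term in the irradiance field.
DEFAULT_DIFFUSE_FRACTION = 0.7

_DEFAULT_ANGLES = {1: (90.0,), 2: (90.0, 210.0), 3: (90.0, 210.0, 330.0)}


@dataclass(frozen=True)
class Geometry:
    """Dome geometry and the camera's sampling of the sample plane.

    Defaults follow the reference build: dome radius R = 14 cm, ROP radius
    r = 6 cm, LED ring distance d = 8 cm, three LEDs in a triangular pattern.
    """

    dome_radius_cm: float = 14.0
    rop_radius_cm: float = 6.0
    led_distance_cm: float = 8.0
    led_angles_deg: tuple[float, ...] = _DEFAULT_ANGLES[3]
    pixel_pitch_mm: float = 0.25

    def __post_init__(self):
        if not (0 < self.rop_radius_cm < self.dome_radius_cm):
            raise ValueError("need 0 < rop_radius_cm < dome_radius_cm")
        if not (0 < self.led_distance_cm < self.dome_radius_cm):
            raise ValueError("need 0 < led_distance_cm < dome_radius_cm")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        object.__setattr__(self, "led_angles_deg",
                           tuple(float(a) for a in self.led_angles_deg))

    @property
    def n_leds(self) -> int:
        return len(self.led_angles_deg)

    def with_n_leds(self, n: int) -> "Geometry":
        """Same geometry with the standard 1/2/3-LED angle pattern."""
        if n not in _DEFAULT_ANGLES:
            raise ValueError("n must be 1, 2 or 3 for the standard patterns")
        return replace(self, led_angles_deg=_DEFAULT_ANGLES[n])


def _default_sensitivity() -> np.ndarray:
    # Silicon webcam with the IR-blocking filter removed: broad response
    # peaking in the green, rolling off into the NIR.
    s = 1.05 * np.exp(-0.5 * ((GRID - 540.0) / 190.0) ** 2)
    return np.clip(s, 0.0, 1.0)


@dataclass
class SensorModel:
    """8-bit camera model: spectral response, gain, offset and noise.

    ``shot_noise_gain`` is the electrons-per-gray-unit equivalent; the shot
    noise SD in gray units at photon signal s is sqrt(s / shot_noise_gain).
    ``flicker_sd`` is the fractional frame-to-frame common-mode jitter of
    the illumination (LED drive stability); set 0 to disable.
    """

    sensitivity: np.ndarray = field(default_factory=_default_sensitivity)
    bit_depth: int = 8
    full_scale: int = 255
    dark_offset: float = 6.0
    read_noise_sd: float = 0.4
    shot_noise_gain: float = 8.0
    gain: float = 30.0
    flicker_sd: float = 0.002

    def __post_init__(self):
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if self.sensitivity.shape != GRID.shape:
            raise ValueError("sensitivity must be sampled on the master grid")
        if np.any(self.sensitivity < 0) or np.any(self.sensitivity > 1):
            raise ValueError("sensitivity must lie in [0, 1]")
        if self.dark_offset < 0:
            raise ValueError("dark_offset must be >= 0")
        for name in ("read_noise_sd", "shot_noise_gain", "gain", "flicker_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, **kwargs) -> "SensorModel":
        """A deterministic sensor: no read/shot noise, no flicker."""
        defaults = dict(read_noise_sd=0.0, shot_noise_gain=0.0, flicker_sd=0.0)
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass
class IrradianceMap:
    """Relative irradiance over the sample plane, mean 1 over the ROP."""

    values: np.ndarray
    pixel_pitch_mm: float
    rop_mask: np.ndarray

    def rop_sd(self) -> float:
        """Sample SD of the field over the ROP (evenness figure of merit)."""
        return float(np.std(self.values[self.rop_mask], ddof=1))


def _plane_coords_mm(size_px: tuple[int, int], pitch_mm: float):
    """Pixel-centre coordinates (mm), origin at the ROP centre, y downward."""
    width, height = size_px
    x = (np.arange(width) - (width - 1) / 2.0) * pitch_mm
    y = (np.arange(height) - (height - 1) / 2.0) * pitch_mm
    return np.meshgrid(x, y)


def illumination_field(geometry: Geometry, diffuse_fraction: float,
                       size_px: tuple[int, int]) -> IrradianceMap:
    """Relative irradiance over the sample plane for a given LED layout.

    ``diffuse_fraction`` of the light arrives via the dome (uniform over the
    plane); the remainder falls off as the inverse square of the in-plane
    distance to each LED's ground position.  The result is normalized to
    mean 1 over the ROP, so the mean gray value of a capture is invariant to
    the LED count while its spatial SD shrinks as LEDs are added.
    """
    if not (0.0 <= diffuse_fraction <= 1.0):
        raise ValueError("diffuse_fraction must be in [0, 1]")
    if geometry.n_leds == 0 and diffuse_fraction < 1.0:
        raise ValueError("no LEDs configured but diffuse_fraction < 1")
    pitch = geometry.pixel_pitch_mm
    xx, yy = _plane_coords_mm(size_px, pitch)
    rop_mask = (xx ** 2 + yy ** 2) <= (geometry.rop_radius_cm * 10.0) ** 2
    if not rop_mask.any():
        raise ValueError("image does not cover any of the ROP")

    field_ = np.full(xx.shape, diffuse_fraction, dtype=float)
    if geometry.n_leds > 0 and diffuse_fraction < 1.0:
        d_mm = geometry.led_distance_cm * 10.0
        direct = np.zeros_like(xx)
        for ang in np.deg2rad(geometry.led_angles_deg):
            lx, ly = d_mm * np.cos(ang), d_mm * np.sin(ang)
            d2 = (xx - lx) ** 2 + (yy - ly) ** 2
            direct += 1.0 / np.maximum(d2, (pitch / 2.0) ** 2)
        direct /= direct[rop_mask].mean()
        field_ += (1.0 - diffuse_fraction) * direct
    field_ /= field_[rop_mask].mean()
    return IrradianceMap(field_, pitch, rop_mask)


def _quantize(signal: np.ndarray, full_scale: int) -> np.ndarray:
    # np.rint rounds half to even.
    return np.clip(np.rint(signal), 0, full_scale).astype(np.uint8)


def _expose(photon: np.ndarray, sensor: SensorModel,
            rng: np.random.Generator) -> np.ndarray:
    """Apply flicker, offset, noise and quantization to a photon signal."""
    flicker = rng.normal(0.0, 1.0)
    photon = photon * (1.0 + sensor.flicker_sd * flicker)
    photon = np.maximum(photon, 0.0)
    signal = photon + sensor.dark_offset
    var = np.full(signal.shape, sensor.read_noise_sd ** 2)
    if sensor.shot_noise_gain > 0:
        var += photon / sensor.shot_noise_gain
    noise = rng.standard_normal(signal.shape) * np.sqrt(var)
    return _quantize(signal + noise, sensor.full_scale)


def noiseless_signal(scene: Scene, band: SpectralBand, sensor: SensorModel,
                     irradiance: np.ndarray) -> np.ndarray:
    """Expected (pre-noise, pre-quantization) signal including dark offset."""
    weights = led_emission_spectrum(band, GRID) * sensor.sensitivity
    refl = scene.reflectance_integral(weights)
    return sensor.gain * irradiance * refl + sensor.dark_offset


def render_band_image(scene: Scene, band: SpectralBand, sensor: SensorModel,
                      geometry: Geometry, seed: int, leds_on: bool = True,
                      diffuse_fraction: float = DEFAULT_DIFFUSE_FRACTION,
                      irradiance: IrradianceMap | None = None) -> BandImage:
    """Render one 8-bit grayscale frame of a scene under one LED band.

    ``leds_on=False`` produces a dark frame (offset plus read noise only).
    Identical inputs and seed produce a bit-identical image.
    """
    rng = np.random.default_rng(seed)
    shape = (scene.height_px, scene.width_px)
    if leds_on:
        if irradiance is None:
            irradiance = illumination_field(
                geometry, diffuse_fraction, (scene.width_px, scene.height_px))
        if irradiance.values.shape != shape:
            raise ValueError("irradiance map shape does not match scene")
        weights = led_emission_spectrum(band, GRID) * sensor.sensitivity
        photon = sensor.gain * irradiance.values * scene.reflectance_integral(weights)
    else:
        photon = np.zeros(shape)
    return BandImage(_expose(photon, sensor, rng), band)


_RGB_CHANNELS = ((610.0, 45.0), (540.0, 40.0), (465.0, 35.0))


def render_color_image(scene: Scene, sensor: SensorModel, geometry: Geometry,
                       seed: int, duty: float = 1.0, leds_on: bool = True,
                       diffuse_fraction: float = DEFAULT_DIFFUSE_FRACTION,
                       irradiance: IrradianceMap | None = None) -> BandImage:
    """Render the white-LED RGB reference frame (H, W, 3)."""
    rng = np.random.default_rng(seed)
    shape = (scene.height_px, scene.width_px)
    channels = []
    if leds_on and irradiance is None:
        irradiance = illumination_field(
            geometry, diffuse_fraction, (scene.width_px, scene.height_px))
    emission = white_led_spectrum(GRID, duty)
    for centre, width in _RGB_CHANNELS:
        if leds_on:
            chan_sens = sensor.sensitivity * np.exp(
                -0.5 * ((GRID - centre) / width) ** 2)
            refl = scene.reflectance_integral(emission * chan_sens)
            photon = sensor.gain * irradiance.values * refl
        else:
            photon = np.zeros(shape)
        channels.append(_expose(photon, sensor, rng))
    return BandImage(np.stack(channels, axis=-1), WHT)
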