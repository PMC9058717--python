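"""Synthetic scenes: per-pixel reflectance spectra for the simulated dome.

A :class:`Scene` is a layered description of the sample plane: a background
reflectance spectrum plus components, each a soft mask with its own
spectrum.  Three built-in fixtures reproduce the calibration and
proof-of-concept targets of the imaging protocol:

``crs``
    A certified reflectance standard: flat 0.99 reflectance at all
    wavelengths, used for sensitivity and saturation calibration.
``pink_disk``
    A pink paper disk (default 7 cm diameter) on a dark background, used
    for the illumination-evenness and temporal-consistency tests.
``colonies``
    A four-compartment Petri dish of agar with bacterial colonies whose
    radii grow monotonically with time.  Colony spectra differ from agar
    first in configurable NIR bands and only later in the visible, so young
    colonies are invisible in an RGB reference but separable by PCA on a
    band stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import GRID


def flat_spectrum(value: float) -> np.ndarray:
    return np.full(GRID.shape, float(value))


def pink_paper_spectrum() -> np.ndarray:
    # Pink paper: high red/blue reflectance with a green absorption dip.
    r = 0.62 - 0.18 * np.exp(-0.5 * ((GRID - 540.0) / 40.0) ** 2)
    return np.clip(r, 0.0, 1.0)


def agar_spectrum() -> np.ndarray:
    # Nutrient agar: mid-gray in the visible, slightly brighter in the NIR.
    r = 0.32 + 0.08 / (1.0 + np.exp(-(GRID - 750.0) / 60.0))
    return np.clip(r, 0.0, 1.0)


@dataclass
class SceneComponent:
    """One layer: a soft mask in [0, 1] and its reflectance spectrum."""

    mask: np.ndarray
    spectrum: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=float)
        self.spectrum = np.clip(np.asarray(self.spectrum, dtype=float), 0.0, 1.0)
        if self.spectrum.shape != GRID.shape:
            raise ValueError("component spectrum must be sampled on the master grid")
        if np.any(self.mask < 0) or np.any(self.mask > 1):
            raise ValueError("component mask must lie in [0, 1]")


@dataclass
class Scene:
    """Per-pixel reflectance over the region of photography.

    Layers are composited painter-style: later components overwrite earlier
    ones where their mask is 1.  Reflectance is therefore bounded to [0, 1]
    everywhere because every layer spectrum is clipped to [0, 1].
    """

    width_px: int
    height_px: int
    background: np.ndarray = field(default_factory=lambda: flat_spectrum(0.05))
    components: list[SceneComponent] = field(default_factory=list)
    time_h: float = 0.0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        self.background = np.clip(np.asarray(self.background, dtype=float), 0.0, 1.0)
        if self.background.shape != GRID.shape:
            raise ValueError("background spectrum must be sampled on the master grid")
        for comp in self.components:
            if comp.mask.shape != (self.height_px, self.width_px):
                raise ValueError("component mask shape must match scene size")

    def reflectance_integral(self, weights: np.ndarray) -> np.ndarray:
        """Per-pixel integral of weights(l) * reflectance(x, y, l) over l.

        ``weights`` is any non-negative spectral weighting on the master
        grid (typically emission x sensitivity); trapezoidal integration.
        """
        weights = np.asarray(weights, dtype=float)
        img = np.full((self.height_px, self.width_px),
                      float(np.trapezoid(weights * self.background, GRID)))
        for comp in self.components:
            val = float(np.trapezoid(weights * comp.spectrum, GRID))
            img = (1.0 - comp.mask) * img + comp.mask * val
        return img

    def reflectance(self, x: int, y: int, lam: float) -> float:
        """Point reflectance at pixel (x, y) and wavelength lam (nm)."""
        r = float(np.interp(lam, GRID, self.background))
        for comp in self.components:
            m = float(comp.mask[y, x])
            r = (1.0 - m) * r + m * float(np.interp(lam, GRID, comp.spectrum))
        return r


def disk_mask(width_px: int, height_px: int, center_px: tuple[float, float],
              radius_px: float) -> np.ndarray:
    """Binary (float) mask of pixels whose centres lie within the circle."""
    xx, yy = np.meshgrid(np.arange(width_px), np.arange(height_px))
    cx, cy = center_px
    return (((xx - cx) ** 2 + (yy - cy) ** 2) <= radius_px ** 2).astype(float)


def _crs_scene(size_px=(480, 480), reflectance=0.99, **_ignored) -> Scene:
    w, h = size_px
    return Scene(w, h, background=flat_spectrum(reflectance))


def _pink_disk_scene(size_px=(480, 480), diameter_mm=70.0,
                     pixel_pitch_mm=0.25, background_reflectance=0.05,
                     **_ignored) -> Scene:
    w, h = size_px
    radius_px = diameter_mm / 2.0 / pixel_pitch_mm
    mask = disk_mask(w, h, ((w - 1) / 2.0, (h - 1) / 2.0), radius_px)
    return Scene(w, h, background=flat_spectrum(background_reflectance),
                 components=[SceneComponent(mask, pink_paper_spectrum())])


def colony_spectrum(t_h: float,
                    nir_bumps=((880.0, 50.0, 0.30), (950.0, 50.0, 0.30)),
                    vis_delta: float = 0.20,
                    vis_onset_h: float = 10.0) -> np.ndarray:
    """Colony reflectance at age ``t_h`` hours.

    NIR contrast (metabolic, water-content driven) appears within the first
    hours; visible contrast (biomass) ramps up only after ``vis_onset_h``.
    """
    r = agar_spectrum()
    g_nir = 1.0 - np.exp(-max(t_h, 0.0) / 3.0)
    for centre, width, delta in nir_bumps:
        r = r + g_nir * delta * np.exp(-0.5 * ((GRID - centre) / width) ** 2)
    g_vis = 1.0 - np.exp(-max(t_h - vis_onset_h, 0.0) / 8.0)
    r = r + g_vis * vis_delta * (GRID < 700.0)
    return np.clip(r, 0.0, 1.0)


def _colonies_scene(size_px=(480, 480), t: float = 0.0, n_colonies: int = 12,
                    seed: int = 0, pixel_pitch_mm: float = 0.25,
                    max_radius_mm=(2.0, 4.0), growth_tau_h: float = 10.0,
                    nir_bumps=((880.0, 50.0, 0.30), (950.0, 50.0, 0.30)),
                    vis_delta: float = 0.20, vis_onset_h: float = 10.0,
                    **_ignored) -> Scene:
    w, h = size_px
    rng = np.random.default_rng(seed)
    components: list[SceneComponent] = []

    # Four-compartment dish: thin dark divider cross over the agar.
    xx, yy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    half_div_px = max(1.0, 0.75 / pixel_pitch_mm)
    divider = ((np.abs(xx - cx) <= half_div_px) |
               (np.abs(yy - cy) <= half_div_px)).astype(float)
    components.append(SceneComponent(divider, flat_spectrum(0.08)))

    # Colonies: one per draw, radius saturating-exponential in time.
    spectrum = colony_spectrum(t, nir_bumps, vis_delta, vis_onset_h)
    margin = 0.12 * min(w, h)
    centers_x = rng.uniform(margin, w - margin, n_colonies)
    centers_y = rng.uniform(margin, h - margin, n_colonies)
    r_max_mm = rng.uniform(max_radius_mm[0], max_radius_mm[1], n_colonies)
    growth = 1.0 - np.exp(-max(t, 0.0) / growth_tau_h)
    for cx_i, cy_i, rm in zip(centers_x, centers_y, r_max_mm):
        radius_px = rm * growth / pixel_pitch_mm
        if radius_px <= 0:
            continue
        components.append(
            SceneComponent(disk_mask(w, h, (cx_i, cy_i), radius_px), spectrum))
    return Scene(w, h, background=agar_spectrum(), components=components,
                 time_h=t)


_FIXTURES = {"crs": _crs_scene, "pink_disk": _pink_disk_scene,
             "colonies": _colonies_scene}


def make_fixture(name: str, **params) -> Scene:
    """Build one of the named fixture scenes; see module docstring."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}") from None
    return builder(**params)
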