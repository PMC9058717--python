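"""Capture protocol: device abstraction, dark subtraction, set and
time-lapse acquisition.

Every band capture follows the dark-subtraction protocol: a LEDs-off dark
frame is grabbed immediately before the illuminated frame and subtracted
pixelwise (clipped below at zero), so the stored image is free of the
sensor's constant offset.  A capture set takes one such image per selected
band, in plan order; the special band label ``WHT`` stores an RGB
white-light reference instead of a grayscale frame.  Time-lapse runs repeat
sets at a fixed start-to-start interval on an injectable clock, writing
each frame as an 8-bit PNG and, optionally, a PCA1 image per set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .bands import SpectralBand
from .errors import CaptureError, DegenerateStackError
from .images import WHT, BandImage, SpectralStack
from .optics_sim import (DEFAULT_DIFFUSE_FRACTION, Geometry, IrradianceMap,
                         SensorModel, illumination_field, render_band_image,
                         render_color_image)
from .scenes import Scene


@runtime_checkable
class DeviceBackend(Protocol):
    """Contract for a capture device (simulated or, elsewhere, hardware)."""

    simulated: bool

    def set_band(self, band: SpectralBand | str, duty: float | None = None) -> None: ...

    def leds_off(self) -> None: ...

    def grab_frame(self, seed: int | None = None) -> np.ndarray: ...


class SimulatedDevice:
    """Software stand-in for the dome: renders frames from a scene.

    ``scene`` may be a static :class:`Scene` or a callable ``t -> Scene``
    for time-evolving fixtures; ``set_time`` re-materializes the scene.
    The irradiance field is cached per geometry, since it depends only on
    geometry and the diffuse fraction.
    """

    simulated = True

    def __init__(self, scene: Scene | Callable[[float], Scene],
                 sensor: SensorModel | None = None,
                 geometry: Geometry | None = None,
                 diffuse_fraction: float = DEFAULT_DIFFUSE_FRACTION):
        self.sensor = sensor if sensor is not None else SensorModel()
        self.geometry = geometry if geometry is not None else Geometry()
        self.diffuse_fraction = diffuse_fraction
        self._scene_fn = scene if callable(scene) else None
        self.scene = scene(0.0) if callable(scene) else scene
        self._band: SpectralBand | str | None = None
        self._irradiance: IrradianceMap | None = None

    def set_time(self, t: float) -> None:
        if self._scene_fn is not None:
            self.scene = self._scene_fn(t)

    def set_band(self, band: SpectralBand | str, duty: float | None = None) -> None:
        if isinstance(band, SpectralBand) and duty is not None:
            band = band.with_duty(duty)
        self._band = band

    def leds_off(self) -> None:
        self._band = None

    def _field(self) -> IrradianceMap:
        size = (self.scene.width_px, self.scene.height_px)
        if self._irradiance is None or self._irradiance.values.shape != size[::-1]:
            self._irradiance = illumination_field(
                self.geometry, self.diffuse_fraction, size)
        return self._irradiance

    def grab_frame(self, seed: int | None = None) -> np.ndarray:
        """Raw 8-bit frame for the current band (dark frame if LEDs off)."""
        if self._band is None:
            img = render_band_image(
                self.scene, SpectralBand("off", 500.0, 10.0, 0.0), self.sensor,
                self.geometry, seed, leds_on=False)
        elif isinstance(self._band, str):
            if self._band != WHT:
                raise ValueError(f"unknown band label {self._band!r}")
            img = render_color_image(
                self.scene, self.sensor, self.geometry, seed,
                diffuse_fraction=self.diffuse_fraction, irradiance=self._field())
        else:
            img = render_band_image(
                self.scene, self._band, self.sensor, self.geometry, seed,
                diffuse_fraction=self.diffuse_fraction, irradiance=self._field())
        return img.pixels


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit 3-channel frame to 8-bit luma (ITU-R BT.601).

    Y = 0.299 R + 0.587 G + 0.114 B, rounded to the nearest integer — the
    same weights the OpenCV BGR2GRAY conversion applies.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) frame")
    y = (0.299 * rgb[..., 0].astype(float) + 0.587 * rgb[..., 1].astype(float)
         + 0.114 * rgb[..., 2].astype(float))
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def capture_band(device: DeviceBackend, band: SpectralBand | str, seed: int,
                 set_index: int = 0, timestamp: float = 0.0) -> BandImage:
    """Dark-subtracted capture of one band: (lit - dark) clipped at zero."""
    dark_seed, lit_seed = _spawn_seeds(seed, 2)
    name = band if isinstance(band, str) else band.name
    try:
        device.leds_off()
        dark = device.grab_frame(dark_seed)
        device.set_band(band)
        lit = device.grab_frame(lit_seed)
    except Exception as exc:  # noqa: BLE001 - re-raise with band identity
        raise CaptureError(f"capture failed for band {name}: {exc}", band=name) from exc
    if dark.shape != lit.shape:
        # Colour capture: the dark grab above was grayscale; re-grab in colour
        # channel space by broadcasting the dark level per channel.
        dark = dark[..., None]
    diff = np.clip(lit.astype(np.int16) - dark.astype(np.int16), 0, 255)
    return BandImage(diff.astype(np.uint8), band, dark_subtracted=True,
                     set_index=set_index, timestamp=timestamp)


def capture_set(device: DeviceBackend, plan: "CapturePlan", set_index: int,
                seed: int, timestamp: float = 0.0) -> SpectralStack:
    """One dark-subtracted image per planned band, in plan order."""
    plan.validate()
    seeds = _spawn_seeds(seed, len(plan.bands))
    images = [capture_band(device, band, s, set_index, timestamp)
              for band, s in zip(plan.bands, seeds)]
    return SpectralStack(images)


@dataclass
class CapturePlan:
    """What to capture: bands, number of sets, and the interval between sets."""

    bands: list[SpectralBand | str]
    n_sets: int = 1
    interval_s: float = 0.0
    pca_per_set: bool = False

    def validate(self) -> None:
        if not self.bands:
            raise ValueError("plan must select at least one band")
        if self.n_sets < 1:
            raise ValueError("n_sets must be >= 1")
        if self.interval_s < 0:
            raise ValueError("interval_s must be >= 0")
        names = [b if isinstance(b, str) else b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("duplicate bands in plan")


class SimulatedClock:
    """Deterministic clock: sleeping advances time instantly."""

    def __init__(self, t0: float = 0.0):
        self._t = float(t0)

    def now(self) -> float:
        return self._t

    def sleep(self, seconds: float) -> None:
        if seconds < 0:
            raise ValueError("cannot sleep a negative duration")
        self._t += seconds


@dataclass
class TimelapseManifest:
    """Record of a time-lapse run: completed sets and every file written."""

    n_sets_completed: int = 0
    files: list[str] = field(default_factory=list)
    timestamps: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"n_sets_completed": self.n_sets_completed, "files": self.files,
                "timestamps": self.timestamps, "warnings": self.warnings,
                "seed": self.seed}


def band_file_name(set_index: int, band_name: str) -> str:
    return f"set{set_index:04d}_{band_name}.png"


def run_timelapse(device: DeviceBackend, plan: CapturePlan,
                  clock: SimulatedClock | None = None,
                  out_dir: str | Path | None = None,
                  seed: int = 0) -> TimelapseManifest:
    """Run a planned time-lapse: ``n_sets`` capture sets, one every
    ``interval_s`` seconds (start-to-start, first set at t = 0).

    Each band image is written as ``set{NNNN}_{band}.png``; with
    ``pca_per_set`` a PCA1 image ``set{NNNN}_PCA1.png`` is written per set.
    If a set fails mid-way the partial set is discarded and the manifest
    records only the completed sets.
    """
    from .analysis import pca_per_set as _pca  # local import: avoid cycle
    from .analysis import rescale_to_8bit
    from .imgio import save_image

    plan.validate()
    clock = clock if clock is not None else SimulatedClock()
    manifest = TimelapseManifest(seed=seed)
    set_seeds = _spawn_seeds(seed, plan.n_sets)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    t0 = clock.now()
    for i in range(plan.n_sets):
        target = t0 + i * plan.interval_s
        if clock.now() < target:
            clock.sleep(target - clock.now())
        if hasattr(device, "set_time"):
            device.set_time(clock.now())
        try:
            stack = capture_set(device, plan, i, set_seeds[i],
                                timestamp=clock.now())
        except CaptureError as exc:
            manifest.warnings.append(
                f"set {i} aborted at band {exc.band}: {exc}")
            break
        written: list[str] = []
        if out_path is not None:
            for img in stack.images:
                p = out_path / band_file_name(i, img.band_name)
                save_image(img, p)
                written.append(str(p))
        if plan.pca_per_set:
            try:
                result = _pca(stack)
                pca_img = rescale_to_8bit(result.pc_images[0], label="PCA1")
                pca_img.set_index = i
                pca_img.timestamp = clock.now()
                if out_path is not None:
                    p = out_path / band_file_name(i, "PCA1")
                    save_image(pca_img, p)
                    written.append(str(p))
            except DegenerateStackError as exc:
                manifest.warnings.append(f"set {i}: PCA skipped ({exc})")
        manifest.files.extend(written)
        manifest.timestamps.append(clock.now())
        manifest.n_sets_completed += 1

    if out_path is not None:
        with open(out_path / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2)
    return manifest
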