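import numpy as np
import pytest

import ledmsi as L

#: Desk-scale render size used throughout the suite (40 x 40 mm field at
#: the default 0.25 mm pixel pitch) — large enough for mm-scale ROIs,
#: small enough that every test renders in milliseconds.
SIZE = (160, 160)
CENTER = ((SIZE[0] - 1) / 2.0, (SIZE[1] - 1) / 2.0)
PITCH = 0.25


def get_band(name: str) -> L.SpectralBand:
    return next(b for b in L.default_band_set() if b.name == name)


@pytest.fixture
def geometry():
    return L.Geometry()


@pytest.fixture
def noiseless_sensor():
    return L.SensorModel.noiseless()


@pytest.fixture
def crs_scene():
    return L.make_fixture("crs", size_px=SIZE)


@pytest.fixture
def pink_scene():
    return L.make_fixture("pink_disk", size_px=SIZE)


@pytest.fixture
def crs_device(crs_scene):
    return L.SimulatedDevice(crs_scene)


@pytest.fixture
def pink_device(pink_scene):
    return L.SimulatedDevice(pink_scene)


def flat_device(value: float = 250.0, size=SIZE) -> L.SimulatedDevice:
    """Noiseless device with a perfectly flat field and CRS scene whose
    632 nm capture at duty 1 reads exactly ``value`` gray units."""
    scene = L.make_fixture("crs", size_px=size)
    sensor = L.SensorModel.noiseless(dark_offset=0.0, gain=1.0)
    k = L.noiseless_signal(scene, get_band("632"), sensor,
                           np.ones(size[::-1]))[0, 0]
    sensor.gain = value / k
    return L.SimulatedDevice(scene, sensor=sensor, diffuse_fraction=1.0)


def brute_roi_mean(image, center, radius):
    """Pixel-enumeration oracle for circular ROI means."""
    px = image.pixels if isinstance(image, L.BandImage) else np.asarray(image)
    cx, cy = center
    vals = [float(px[y, x])
            for y in range(px.shape[0]) for x in range(px.shape[1])
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2]
    return np.mean(vals) if vals else None


def brute_radial_profile(px, center, step_mm, max_radius_mm, pitch_mm):
    """Independent cumulative-circle profile by full pixel enumeration."""
    px = np.asarray(px, dtype=float)
    cx, cy = center
    radii = np.arange(step_mm, max_radius_mm + step_mm / 2.0, step_mm)
    mgv, sd = [], []
    yy, xx = np.indices(px.shape)
    dist = np.hypot(xx - cx, yy - cy) * pitch_mm
    for r in radii:
        vals = px[dist <= r]
        if vals.size == 0:
            mgv.append(np.nan)
            sd.append(np.nan)
        else:
            mgv.append(vals.mean())
            sd.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
    return radii, np.array(mgv), np.array(sd)
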