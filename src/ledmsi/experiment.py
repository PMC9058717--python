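"""End-to-end protocol driver: runs one named QC or analysis protocol on
the simulated device and writes images, reports and a manifest.

Re-running the same configuration and seed reproduces byte-identical
grayscale outputs; the manifest records the configuration hash, the seed,
and every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np

from .acquisition import (CapturePlan, SimulatedClock, SimulatedDevice,
                          capture_band, run_timelapse, _spawn_seeds)
from .analysis import fit_reflectance_analyte, simulate_nitrogen_mgv
from .bands import SpectralBand
from .config import RunConfig
from .errors import ConfigError
from .imgio import load_image, save_image, save_table_csv
from .qc import (CONSISTENCY_SD_PCT_BOUND, CircularROI, adjust_intensity,
                 band_sensitivity, consistency_stats, radial_profile)
from .scenes import make_fixture

log = logging.getLogger("ledmsi")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _device(config: RunConfig, scene_or_fn) -> SimulatedDevice:
    return SimulatedDevice(scene_or_fn, sensor=config.sensor,
                           geometry=config.geometry,
                           diffuse_fraction=config.diffuse_fraction)


def _fixture_params(config: RunConfig) -> dict:
    params = dict(config.fixture.params)
    params.setdefault("pixel_pitch_mm", config.geometry.pixel_pitch_mm)
    return params


def _center(scene) -> tuple[float, float]:
    return ((scene.width_px - 1) / 2.0, (scene.height_px - 1) / 2.0)


def _default_roi(scene, config: RunConfig) -> CircularROI:
    # A 30 mm-radius ROI centred on the fixture, well inside the 7 cm disk.
    return CircularROI(_center(scene), 30.0 / config.geometry.pixel_pitch_mm)


def run_experiment(config: RunConfig, out: str | Path | None = None) -> dict:
    """Execute one protocol end-to-end; returns the manifest dict."""
    out_dir = Path(out if out is not None else config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = _PROTOCOLS.get(config.protocol)
    if runner is None:
        raise ConfigError(f"unknown protocol {config.protocol!r}")
    log.info("protocol=%s seed=%d out=%s", config.protocol, config.seed, out_dir)
    files, report = runner(config, out_dir)

    manifest = {
        "protocol": config.protocol,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "files": sorted(str(f) for f in files),
        "report": report,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _run_evenness(config: RunConfig, out_dir: Path):
    """Illumination evenness: pink disk under 632 nm with 1, 2, 3 LEDs."""
    band = config.band_by_name("632")
    params = _fixture_params(config)
    scene = make_fixture("pink_disk", **params)
    files: list[Path] = []
    report: dict = {"per_leds": {}}
    seeds = _spawn_seeds(config.seed, 3)
    for n in (1, 2, 3):
        geo = config.geometry.with_n_leds(n)
        device = SimulatedDevice(scene, sensor=config.sensor, geometry=geo,
                                 diffuse_fraction=config.diffuse_fraction)
        img = capture_band(device, band, seeds[n - 1])
        png = out_dir / f"evenness_{n}led.png"
        save_image(img, png)
        files += [png, png.with_suffix(".json")]
        profile = radial_profile(img, _center(scene),
                                 pixel_pitch_mm=geo.pixel_pitch_mm)
        csv_path = out_dir / f"profile_{n}led.csv"
        rows = [{"radius_mm": r, "mgv": m, "sd": s}
                for r, m, s in zip(profile.radii_mm, profile.mgv, profile.sd)]
        save_table_csv(csv_path, rows)
        files.append(csv_path)
        final = -1
        report["per_leds"][str(n)] = {
            "final_radius_mm": float(profile.radii_mm[final]),
            "mgv_final": float(profile.mgv[final]),
            "sd_final": float(profile.sd[final]),
        }
        log.info("evenness %d LED(s): MGV %.1f SD %.2f", n,
                 report["per_leds"][str(n)]["mgv_final"],
                 report["per_leds"][str(n)]["sd_final"])
    return files, report


def _run_sensitivity(config: RunConfig, out_dir: Path):
    """Band sensitivity on the CRS, with auto-adjustment of saturated bands."""
    scene = make_fixture("crs", **_fixture_params(config))
    device = _device(config, scene)
    roi = _default_roi(scene, config)
    seeds = _spawn_seeds(config.seed, 2)
    curve = band_sensitivity(device, config.bands, roi, seed=seeds[0])
    adjusted = []
    adj_seeds = _spawn_seeds(seeds[1], len(curve.entries))
    for entry, s in zip(curve.entries, adj_seeds):
        if entry.saturated:
            band = config.band_by_name(entry.band_name)
            result = adjust_intensity(device, band, roi, seed=s)
            entry.final_duty = result.duty
            entry.mgv = result.mgv
            adjusted.append({"band": entry.band_name, "duty": result.duty,
                             "mgv": result.mgv, "iterations": result.iterations})
            log.info("adjusted band %s: duty %.3f MGV %.1f",
                     entry.band_name, result.duty, result.mgv)
    csv_path = out_dir / "sensitivity.csv"
    save_table_csv(csv_path, curve.as_rows())
    report = {"entries": curve.as_rows(), "adjusted": adjusted}
    return [csv_path], report


def _run_consistency(config: RunConfig, out_dir: Path):
    """Temporal consistency: repeated captures of a static pink disk."""
    params = _fixture_params(config)
    scene = make_fixture(config.fixture.name, **params)
    device = _device(config, scene)
    band_name = config.plan.bands[0]
    band = config.band_by_name(band_name)
    plan = CapturePlan(bands=[band], n_sets=config.plan.n_sets,
                       interval_s=config.plan.interval_s)
    frames_dir = out_dir / "frames"
    manifest = run_timelapse(device, plan, SimulatedClock(), frames_dir,
                             seed=config.seed)
    frames = [load_image(p) for p in manifest.files if p.endswith(".png")]
    roi = _default_roi(scene, config)
    stats = consistency_stats(frames, roi)
    report = {"n_frames": stats.n_frames, "mean_mgv": stats.mean_mgv,
              "sd_mgv": stats.sd_mgv, "sd_pct": stats.sd_pct,
              "bound_pct": CONSISTENCY_SD_PCT_BOUND,
              "within_bound": stats.within_bound}
    log.info("consistency: %d frames, MGV %.2f, SD %.3f%%",
             stats.n_frames, stats.mean_mgv, stats.sd_pct)
    files = [Path(f) for f in manifest.files] + [frames_dir / "manifest.json"]
    files += [Path(f).with_suffix(".json") for f in manifest.files]
    return files, report


def _run_timelapse_pca(config: RunConfig, out_dir: Path):
    """Colony development time-lapse with one PCA1 image per set."""
    params = _fixture_params(config)
    params.setdefault("seed", config.seed)

    def scene_fn(t_s: float):
        return make_fixture("colonies", t=t_s / 3600.0, **params)

    device = _device(config, scene_fn)
    bands = [config.band_by_name(n) if n != "WHT" else "WHT"
             for n in config.plan.bands]
    plan = CapturePlan(bands=bands, n_sets=config.plan.n_sets,
                       interval_s=config.plan.interval_s, pca_per_set=True)
    sets_dir = out_dir / "sets"
    manifest = run_timelapse(device, plan, SimulatedClock(), sets_dir,
                             seed=config.seed)
    report = {"n_sets": manifest.n_sets_completed,
              "timestamps_s": manifest.timestamps,
              "warnings": manifest.warnings}
    files = [Path(f) for f in manifest.files] + [sets_dir / "manifest.json"]
    files += [Path(f).with_suffix(".json") for f in manifest.files]
    return files, report


def _run_analyte(config: RunConfig, out_dir: Path):
    """Synthetic red-band reflectance vs nitrogen regression."""
    nitrogen, mgv, labels = simulate_nitrogen_mgv(seed=config.seed)
    fit = fit_reflectance_analyte(mgv, nitrogen)
    csv_path = out_dir / "nitrogen_mgv.csv"
    rows = [{"crop": c, "nitrogen_pct": f"{n:.4f}", "mgv": f"{m:.3f}"}
            for c, n, m in zip(labels, nitrogen, mgv)]
    save_table_csv(csv_path, rows)
    report = {"slope": fit.slope, "intercept": fit.intercept,
              "pearson_r": fit.pearson_r, "n": fit.n}
    log.info("analyte fit: slope %.4f r %.3f n %d", fit.slope, fit.pearson_r,
             fit.n)
    return [csv_path], report


_PROTOCOLS = {
    "evenness": _run_evenness,
    "sensitivity": _run_sensitivity,
    "consistency": _run_consistency,
    "timelapse-pca": _run_timelapse_pca,
    "analyte": _run_analyte,
}
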