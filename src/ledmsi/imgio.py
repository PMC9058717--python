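"""PNG and CSV input/output.

Band images are stored as lossless 8-bit PNGs (single channel for spectral
bands, RGB for the white reference) with capture metadata in a JSON sidecar
next to the image (``frame.png`` + ``frame.json``).  Spectra and curves are
exchanged as two-column CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .bands import SpectralBand
from .errors import FormatError
from .images import BandImage

UNKNOWN_BAND = "unknown"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_image(image: BandImage, path: str | Path) -> Path:
    """Write a BandImage as 8-bit PNG plus a JSON metadata sidecar."""
    path = Path(path)
    mode = "RGB" if image.is_color else "L"
    Image.fromarray(image.pixels, mode=mode).save(path, format="PNG")
    band = image.band
    meta = {
        "band": band if isinstance(band, str) else {
            "name": band.name, "peak_nm": band.peak_nm,
            "fwhm_nm": band.fwhm_nm, "duty": band.duty},
        "dark_subtracted": image.dark_subtracted,
        "set_index": image.set_index,
        "timestamp": image.timestamp,
    }
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def load_image(path: str | Path) -> BandImage:
    """Read a PNG band image; a missing sidecar yields unknown metadata."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB" if im.mode == "RGB" else "L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit PNG")
    side = _sidecar(path)
    if side.exists():
        try:
            meta = json.loads(side.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"corrupt sidecar {side}: {exc}") from exc
        band = meta.get("band", UNKNOWN_BAND)
        if isinstance(band, dict):
            band = SpectralBand(**band)
        return BandImage(arr, band,
                         dark_subtracted=bool(meta.get("dark_subtracted", False)),
                         set_index=int(meta.get("set_index", 0)),
                         timestamp=float(meta.get("timestamp", 0.0)))
    return BandImage(arr, UNKNOWN_BAND)


def save_spectrum_csv(path: str | Path, wavelength_nm, value,
                      value_name: str = "value") -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", value_name])
        for wl, v in zip(wavelength_nm, value):
            writer.writerow([f"{wl:g}", f"{v:.8g}"])
    return path


def load_spectrum_csv(path: str | Path):
    """Read a two-column (wavelength_nm, value) CSV; returns two arrays."""
    path = Path(path)
    try:
        data = np.genfromtxt(path, delimiter=",", skip_header=1, dtype=float)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse spectrum CSV {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[1] < 2 or np.isnan(data[:, :2]).any():
        raise FormatError(f"{path}: expected two numeric columns with header")
    return data[:, 0], data[:, 1]


def save_table_csv(path: str | Path, rows: list[dict]) -> Path:
    """Write a list of homogeneous dicts as CSV."""
    path = Path(path)
    if not rows:
        raise ValueError("no rows to write")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return path
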