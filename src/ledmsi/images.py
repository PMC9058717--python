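"""In-memory image containers: single-band frames and co-registered stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import SpectralBand

#: Sentinel band label for the white-LED RGB reference image.
WHT = "WHT"


@dataclass
class BandImage:
    """One 8-bit frame plus capture metadata.

    ``pixels`` is uint8, shape (H, W) for grayscale band images or (H, W, 3)
    for the white/colour reference.
    """

    pixels: np.ndarray
    band: SpectralBand | str
    dark_subtracted: bool = False
    set_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError("BandImage pixels must be uint8")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("BandImage pixels must be 2-D or (H, W, 3)")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("colour BandImage must have 3 channels")
        if self.set_index < 0:
            raise ValueError("set_index must be >= 0")

    @property
    def band_name(self) -> str:
        return self.band if isinstance(self.band, str) else self.band.name

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class SpectralStack:
    """Ordered, co-registered band images from one capture set."""

    images: list[BandImage] = field(default_factory=list)

    def __post_init__(self):
        if not self.images:
            raise ValueError("SpectralStack needs at least one image")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"all images in a stack must share one shape, got {shapes}")
        names = [im.band_name for im in self.images]
        if len(set(names)) != len(names):
            raise ValueError("duplicate bands in stack")

    def __len__(self) -> int:
        return len(self.images)

    def spectral_images(self) -> list[BandImage]:
        """Grayscale single-band images only (excludes the colour reference)."""
        return [im for im in self.images if not im.is_color]

    def as_array(self) -> np.ndarray:
        """Stack the grayscale band images into (H, W, n_bands) float64."""
        grays = self.spectral_images()
        if not grays:
            raise ValueError("stack has no grayscale band images")
        return np.stack([im.pixels.astype(float) for im in grays], axis=-1)

    def band_names(self) -> list[str]:
        return [im.band_name for im in self.spectral_images()]
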