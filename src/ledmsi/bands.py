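"""LED band definitions and emission spectra.

Each LED channel is described by the wavelength of its emission peak, the
full width at half maximum (FWHM) of the peak, and a PWM duty cycle acting
as a linear intensity fraction.  Channels are named by their peak wavelength
("525", "660", ...).  Emission profiles are modelled as Gaussians, which is
a good approximation for single-colour LEDs at the ~10 nm widths used here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

#: Master wavelength grid for all spectral integrals, 1 nm steps (nm).
GRID = np.arange(350.0, 1100.0 + 0.5, 1.0)

#: Converts a FWHM to the Gaussian width parameter sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Default 12-channel band set: peak wavelengths in nm, visible through NIR.
DEFAULT_PEAKS_NM = (419, 450, 470, 500, 525, 560, 592, 632, 660, 740, 880, 950)

#: Default channel band width (average FWHM of the LED set), nm.
DEFAULT_FWHM_NM = 10.0


@dataclass(frozen=True)
class SpectralBand:
    """One LED channel.

    Parameters
    ----------
    name : str
        Label, conventionally the peak wavelength as text ("632").
    peak_nm : float
        Wavelength of the emission maximum, nm, within [350, 1100].
    fwhm_nm : float
        Full width at half maximum of the emission peak, nm, > 0.
    duty : float
        PWM duty cycle in [0, 1]; linear intensity fraction.
    """

    name: str
    peak_nm: float
    fwhm_nm: float = DEFAULT_FWHM_NM
    duty: float = 1.0

    def __post_init__(self):
        if not (350.0 <= self.peak_nm <= 1100.0):
            raise ValueError(f"peak_nm must be in [350, 1100], got {self.peak_nm}")
        if not self.fwhm_nm > 0:
            raise ValueError(f"fwhm_nm must be > 0, got {self.fwhm_nm}")
        if not (0.0 <= self.duty <= 1.0):
            raise ValueError(f"duty must be in [0, 1], got {self.duty}")

    def with_duty(self, duty: float) -> "SpectralBand":
        """Return a copy of this band at a different duty cycle."""
        return replace(self, duty=duty)


def default_band_set(fwhm_nm: float = DEFAULT_FWHM_NM,
                     duty: float = 1.0) -> list[SpectralBand]:
    """The default 12-channel band set, named by peak wavelength."""
    return [SpectralBand(str(p), float(p), fwhm_nm, duty) for p in DEFAULT_PEAKS_NM]


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return grid


def led_emission_spectrum(band: SpectralBand, grid: np.ndarray) -> np.ndarray:
    """Relative emission spectrum of one LED channel on a wavelength grid.

    A Gaussian centred at ``band.peak_nm`` whose half-maximum crossings are
    separated by ``band.fwhm_nm``, scaled by the duty cycle so the peak value
    equals ``band.duty``.
    """
    grid = _validate_grid(grid)
    sigma = band.fwhm_nm * FWHM_TO_SIGMA
    return band.duty * np.exp(-0.5 * ((grid - band.peak_nm) / sigma) ** 2)


def white_led_spectrum(grid: np.ndarray, duty: float = 1.0) -> np.ndarray:
    """Emission of the white reference LED: blue die plus phosphor hump."""
    grid = _validate_grid(grid)
    blue = np.exp(-0.5 * ((grid - 450.0) / 12.0) ** 2)
    phosphor = 0.65 * np.exp(-0.5 * ((grid - 560.0) / 60.0) ** 2)
    return duty * (blue + phosphor)
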