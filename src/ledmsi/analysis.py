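"""Per-set PCA of band stacks, pseudo-colouring, ROI statistics and the
single-band reflectance-vs-analyte regression.

The dimension reduction treats every pixel of a co-registered band stack as
an observation and every band as a variable.  Bands are centred by their
means but not variance-scaled (all bands share one physical 8-bit gray
scale), so the components come from the eigendecomposition of the
band-by-band covariance matrix.  The first component's score image (PCA1)
concentrates most of the across-band variance and is what the acquisition
pipeline writes per capture set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateStackError
from .images import BandImage, SpectralStack
from .qc import CircularROI, roi_mgv


@dataclass
class PCAResult:
    """Covariance PCA of one band stack.

    ``pc_images[k]`` is the score image of component k; ``loadings[:, k]``
    its unit-norm band-weight vector; ``explained_variance_ratio`` covers
    all components and sums to 1.
    """

    pc_images: np.ndarray            # (n_components, H, W)
    loadings: np.ndarray             # (n_bands, n_components)
    explained_variance_ratio: np.ndarray  # (n_bands,), all components
    eigenvalues: np.ndarray          # (n_bands,), descending
    band_means: np.ndarray           # (n_bands,)
    band_names: list[str]


def pca_per_set(stack: SpectralStack, n_components: int | None = None) -> PCAResult:
    """Pixelwise covariance PCA of a spectral stack.

    Pixels are observations, bands variables; columns are centred by band
    mean only.  Components are sorted by descending eigenvalue and each
    loading vector's sign is fixed so its largest-magnitude entry is
    positive, making score images reproducible across platforms.
    """
    data = stack.as_array()            # (H, W, n_bands)
    h, w, nb = data.shape
    if nb < 2:
        raise ValueError("PCA needs at least 2 bands")
    if n_components is None:
        n_components = nb
    if not (1 <= n_components <= nb):
        raise ValueError("n_components must be in [1, n_bands]")

    x = data.reshape(-1, nb)
    means = x.mean(axis=0)
    xc = x - means
    cov = (xc.T @ xc) / (xc.shape[0] - 1)
    if np.trace(cov) <= 0:
        raise DegenerateStackError("stack has zero total variance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # Deterministic sign: largest-|entry| of each loading vector positive.
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                         np.arange(nb)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    scores = xc @ evecs[:, :n_components]
    return PCAResult(
        pc_images=scores.T.reshape(n_components, h, w),
        loadings=evecs[:, :n_components],
        explained_variance_ratio=evals / evals.sum(),
        eigenvalues=evals,
        band_means=means,
        band_names=stack.band_names(),
    )


def rescale_to_8bit(score_image: np.ndarray, label: str = "PCA1") -> BandImage:
    """Linear min-to-0 / max-to-255 rescale of a score image, rounded
    half-to-even.  A constant image maps to all zeros."""
    img = np.asarray(score_image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("score image must be finite")
    lo, hi = img.min(), img.max()
    if hi == lo:
        out = np.zeros(img.shape, dtype=np.uint8)
    else:
        out = np.clip(np.rint((img - lo) * 255.0 / (hi - lo)), 0, 255).astype(np.uint8)
    return BandImage(out, label)


#: Anchor colours (dark blue -> red) interpolated for any shade count.
_PALETTE_ANCHORS = np.array([
    (0, 0, 128), (0, 128, 255), (0, 255, 0),
    (255, 255, 0), (255, 128, 0), (255, 0, 0)], dtype=float)


def shades_palette(n_shades: int) -> list[tuple[int, int, int]]:
    """A blue-to-red palette of ``n_shades`` distinct RGB colours."""
    t = np.linspace(0.0, 1.0, n_shades)
    anchors_t = np.linspace(0.0, 1.0, len(_PALETTE_ANCHORS))
    rgb = np.stack([np.interp(t, anchors_t, _PALETTE_ANCHORS[:, c])
                    for c in range(3)], axis=1)
    return [tuple(int(round(v)) for v in row) for row in rgb]


@dataclass
class PseudoColorImage:
    indices: np.ndarray                      # uint8 bin per pixel
    palette: list[tuple[int, int, int]]

    def to_rgb(self) -> np.ndarray:
        return np.asarray(self.palette, dtype=np.uint8)[self.indices]


def pseudo_color(image: BandImage | np.ndarray,
                 n_shades: int = 6) -> PseudoColorImage:
    """Bin an 8-bit image into ``n_shades`` equal-width intensity shades.

    Value v falls in bin floor(v * n_shades / 256); bins are half-open with
    255 landing in the last bin.  Returns the bin index image plus the
    palette, so the false-colour rendering is reproducible.
    """
    if not (2 <= n_shades <= 256):
        raise ValueError("n_shades must be in [2, 256]")
    px = image.pixels if isinstance(image, BandImage) else np.asarray(image)
    if px.dtype != np.uint8:
        raise ValueError("pseudo_color expects an 8-bit image")
    indices = (px.astype(np.uint16) * n_shades // 256).astype(np.uint8)
    return PseudoColorImage(indices, shades_palette(n_shades))


def roi_mean(image: BandImage | np.ndarray, center_px: tuple[float, float],
             radius_px: float) -> float:
    """Mean gray value of pixels whose centres lie within the circle."""
    return roi_mgv(image, CircularROI(center_px, radius_px))


@dataclass
class AnalyteFit:
    """Ordinary least-squares fit of analyte concentration vs band MGV."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    stderr: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_reflectance_analyte(mgv, analyte) -> AnalyteFit:
    """OLS regression of reflectance MGV (x) against analyte content (y).

    Used for the single-band chemometric check: red-band reflectance of
    dried ground leaf samples falls as Kjeldahl nitrogen content rises, so
    the fitted slope and Pearson r are expected to be negative.
    """
    x = np.asarray(mgv, dtype=float)
    y = np.asarray(analyte, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("mgv and analyte must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in inputs")
    res = stats.linregress(x, y)
    return AnalyteFit(float(res.slope), float(res.intercept),
                      float(res.rvalue), int(x.size), float(res.stderr))


#: Approximate leaf nitrogen ranges (% dry mass) for the four crop types of
#: the synthetic chemometric data set.
_CROP_NITROGEN = {"cocoa": (1.8, 0.35), "rubber": (3.0, 0.40),
                  "banana": (2.6, 0.35), "chrysanthemum": (4.3, 0.45)}


def simulate_nitrogen_mgv(n_samples: int = 120, seed: int = 0,
                          slope: float = -28.0, intercept: float = 215.0,
                          noise_sd: float = 7.0):
    """Synthetic red-band reflectance vs Kjeldahl nitrogen data set.

    Draws ``n_samples`` leaf samples across four crop types with
    crop-specific nitrogen levels and generates the 660 nm ROI MGV from a
    negative linear response plus Gaussian measurement noise.

    Returns ``(nitrogen_pct, mgv, crop_labels)``.
    """
    rng = np.random.default_rng(seed)
    crops = list(_CROP_NITROGEN)
    labels = [crops[i % len(crops)] for i in range(n_samples)]
    nitrogen = np.array([rng.normal(*_CROP_NITROGEN[c]) for c in labels])
    nitrogen = np.clip(nitrogen, 0.5, 6.5)
    mgv = intercept + slope * nitrogen + rng.normal(0.0, noise_sd, n_samples)
    mgv = np.clip(mgv, 0.0, 255.0)
    return nitrogen, mgv, labels
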