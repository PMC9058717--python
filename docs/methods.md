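# Methods

## Optical forward model

A scene is a layered map of per-pixel reflectance spectra `R(x, y, λ)` on
a 1 nm wavelength grid from 350 to 1100 nm; layers are composited
painter-style and every layer spectrum is clipped to [0, 1], so
reflectance is bounded everywhere. The noiseless signal of band `b` is

    s(x, y) = g · E(x, y) · ∫ L_b(λ) · R(x, y, λ) · S(λ) dλ + D

with trapezoidal integration on the 1 nm grid. `L_b` is a Gaussian whose
peak value equals the PWM duty cycle and whose half-maximum crossings are
separated by the channel FWHM; `S` is the sensor's relative spectral
sensitivity, modelled as a broad Gaussian peaking near 540 nm (clipped at
1) that rolls off into the NIR — the shape of a silicon webcam with its
IR-blocking filter removed. Gain `g` (default 30 gray units per
band-integrated reflectance unit) is chosen so the brightest visible
channels saturate an ideal reflector at full duty, which is the regime the
intensity-adjustment calibration exists for.

The irradiance field `E` mixes a uniform dome-diffused term with per-LED
direct terms that fall off as the inverse square of the in-plane distance
to each LED's ground position (ring radius 8 cm, default angles 90°, 210°,
330°). The mixing weight `diffuse_fraction` defaults to 0.7: mostly
dome-diffused light with enough direct contribution that the 1 vs 3 LED
evenness contrast is clearly visible. `E` is normalized to mean 1 over the
ROP (radius 6 cm), making the ROI mean gray value invariant to LED count —
only the spatial SD changes (0.134 → 0.075 → 0.029 for 1 → 2 → 3 LEDs at
defaults).

## Noise and quantization

Three stochastic terms, each seeded explicitly (no global RNG state):

- read noise: Gaussian, SD 0.4 gray units;
- shot noise: Gaussian approximation with variance `photon_signal / k`,
  `k = 8` electrons per gray unit;
- illumination flicker: one multiplicative Gaussian factor per frame with
  fractional SD 0.002, modelling LED drive stability.

The flicker term matters for the temporal-consistency statistic: pixel
noise averages out over a many-thousand-pixel ROI (it alone would put the
relative SD of the ROI MGV near 0.004%), so frame-to-frame variation of a
real device is dominated by common-mode drive/exposure fluctuation. 0.2%
is a realistic stability figure for PWM-driven LEDs and places the
100-frame statistic near 0.2%, comfortably inside the 0.5% QC bound
without making the test vacuous.

Signals are rounded half-to-even and clipped to [0, 255]; every rendered
pixel is an 8-bit integer. Dark frames contain offset (default 6 gray
units) plus read noise only. Identical inputs and seed give bit-identical
frames.

## Fixtures

- **crs** — flat 0.99 reflectance at all wavelengths (certified
  reflectance standard).
- **pink_disk** — a disk (default 70 mm diameter, the figure-caption value;
  the diameter is a parameter because the protocol text also mentions
  60 mm) of pink paper: high red/blue reflectance with a green absorption
  dip, on a 0.05 background.
- **colonies** — agar with a dark four-compartment divider cross and
  randomly placed colonies whose radii grow as
  `r_max · (1 − exp(−t/τ))`, τ = 10 h, `r_max` 2–4 mm: zero area at t = 0,
  monotone growth. Colony reflectance differs from agar first in two NIR
  bumps (880/950 nm, appearing with a 3 h time constant) and only after
  10 h in the visible, so young colonies are separable by PCA on a NIR
  band stack while invisible in the white-light RGB reference.

What the simulator does *not* emulate: auto white balance/exposure (the
simulated sensor is fixed-gain, keeping runs deterministic), lens
distortion and vignetting, dome inter-reflection beyond the single
diffuse/direct mixture, spectral structure of real colony pigments, and
any registration error (stacks are perfectly co-registered, as with a
fixed camera). Tests passing here therefore validate the protocol logic
and numerics, not radiometric accuracy on a physical build.

## Acquisition conventions

- One dark frame is captured immediately before every illuminated frame
  and subtracted pixelwise, clipped below at zero; only the difference is
  stored.
- The white reference (band label `WHT`) is stored as RGB; all band images
  are single-channel. RGB→gray conversion uses the BT.601 luma weights
  (0.299, 0.587, 0.114), rounded to the nearest integer.
- Time-lapse intervals are start-to-start with the first set at t = 0, on
  an injectable clock (a simulated clock advances instantly, so the
  100 × 10 s consistency run takes seconds of wall time).
- Files are named `set{NNNN}_{band}.png` (PCA output `set{NNNN}_PCA1.png`)
  with capture metadata in a JSON sidecar per image; names sort by
  (set, band).

## QC conventions

- Radial profiles use cumulative circles (all pixels within radius r, not
  annuli), radii from 0.1 mm in 0.1 mm steps to 70 mm by default. A pixel
  belongs to a circle iff its centre is within r — no anti-aliased
  weighting. Circles containing no pixel centre yield NaN; a single pixel
  yields SD 0.
- All SDs are sample SDs (ddof = 1), including the per-frame MGV SD of the
  consistency statistic. The 0.5% consistency bound is a named constant
  reported alongside the statistic, not a hard-coded pass/fail in the
  library.
- Saturation is detected on the *lit* frame before dark subtraction: a
  band is saturated when its ROI MGV rounds to full scale (≥ 254.5). With
  noise, a clipped channel leaves a few pixels just below 255, so strict
  equality would under-detect.
- The intensity-adjustment loop rescales duty by `0.98 · target /
  measured` (saturated measurements read as 255), never raises duty above
  its initial value, and reports a calibration error after 8 measurements.
  Because a saturated measurement is indistinguishable from "at least
  255", signals beyond ≈1.8× full scale need more than 8 back-off steps;
  the calibration protocol starts from the default-gain saturation level
  (≈1.2×), which converges in 3–5 captures.
- FWHM is the distance between the two half-maximum crossings flanking the
  global peak, each located by linear interpolation between adjacent
  samples; truncated peaks raise an error rather than extrapolate.

## PCA conventions

Pixels are observations, bands variables; columns are centred by band mean
and *not* variance-scaled — all bands share one physical 8-bit gray scale,
so covariance PCA is the appropriate convention. Components come from the
eigendecomposition of the band×band covariance matrix (ddof = 1);
eigenvalues are clipped at zero and sorted descending; each loading
vector's sign is fixed so its largest-magnitude entry is positive, making
PCA1 images reproducible across platforms. An all-constant stack raises a
degenerate-input error (surfaced as a per-set warning by the time-lapse
runner rather than silently writing a blank image). Score images are
written after a min→0/max→255 linear rescale (constant input maps to 0);
only PCA1 is written by the pipeline, the full decomposition is available
programmatically.

Pseudo-colouring bins an 8-bit value v into `floor(v · n/256)` of n
half-open bins (255 in the last) and emits a fixed blue-to-red palette
interpolated from six documented anchor colours, so the 6-shade rendering
is monotone in intensity and reproducible.

## Synthetic analyte data

The chemometric check uses 120 synthetic samples across four crop types
(cocoa, rubber, banana, chrysanthemum) with crop-specific nitrogen levels
(means 1.8–4.3 %N) and a 660 nm ROI MGV generated as
`215 − 28·N + ε`, ε ~ N(0, 7). The slope sign encodes the underlying
optics (more nitrogen → more chlorophyll → stronger red absorption →
lower reflectance); its magnitude is a plausible invention, not a
calibrated value, so only sign and correlation strength are asserted.

## Problem sizes and determinism

Library defaults render 480×480 px frames (0.25 mm pixel pitch, a 12 cm
field). The test suite and the acceptance script run the same procedures
at 160–240 px — the statistics they check (ROI means over thousands of
pixels, SD ratios, eigenstructure) are size-stable well below that, and
every procedure then completes in milliseconds. Every stochastic
operation takes an explicit seed; child seeds are derived with
`numpy.random.SeedSequence`, and a run configuration plus master seed
reproduces byte-identical grayscale outputs.

## Known limitations

- The direct-illumination term is an in-plane inverse-square heuristic,
  not ray-traced dome optics; it reproduces the qualitative evenness
  behaviour, not measured profiles.
- The shot-noise Gaussian approximation is poor below ~10 gray units;
  dark-frame statistics are dominated by read noise by design.
- The adjustment loop's saturated back-off is geometric (factor ≈ 0.92 per
  step), slow for deeply saturated signals (see QC conventions).
- The default 12-band wavelength list is a declared convention of this
  package; seven of the peaks are standard single-colour LED wavelengths
  and the rest fill the visible–NIR range.
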