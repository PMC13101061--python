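# Methods

This note documents the models behind `diffuscope`, the parameter choices
that matter, the numerical conventions, and the limits of what the
synthetic experiments demonstrate.

## Paraxial model (`diffuscope.optics`)

The eye is the reduced 60 D thin-lens model (`f_eye` = 16.7 mm); refractive
error is represented as an axial displacement Δz of the fundus from the
back focal plane, and the defocus error in diopters is the vergence
difference ε = 1000·(1/(f − Δz) − 1/f). All distances are millimetres
internally; the single mm→m conversion (factor 1000) lives inside
`defocus_error`, so diopters never mix with 1/mm elsewhere. Sign
convention: positive Δz moves the fundus toward the lens (shorter,
hyperopic eye, ε > 0). The bench model cornea (25.4 mm) and the HEINE
model eye (18 mm) are alternative `f_lens` constants, not separate code
paths.

Everything downstream of the cornea is one fixed ray-transfer matrix
[[A, B], [C, D]] = [[1.340, −40.98 mm], [0.0125 mm⁻¹, 0.3654]] plus
free-space propagations. The conjugate fundus plane, magnification and
object pixel size follow from the imaging condition (see README for the
three formulas). Useful invariants, all enforced by tests:

* the composed fundus→F″ matrix has |B-element| < 1e−9 mm at the returned
  conjugate distance across the whole calibration sweep;
* `displacement_for_defocus` is the exact algebraic inverse of
  `defocus_error` (round trip to 1e−9 D);
* theoretical resolution × pixel size is constant in ε — the resolution
  model is *purely* inverse magnification, anchored at 12.5 lp/mm for the
  emmetropic eye.

`fov_estimate` converts a pixel count through R(ε) to a visual cone angle
2·atan(n·R/2/f_eye). It ignores pupil-relay vignetting, so for a full
sensor width it returns the sensor-limited upper bound, not the ~40°
vignetting-limited field of a real instrument; it is deliberately excluded
from quantitative acceptance.

## Diffuser and caustic simulation (`diffuscope.diffuser`)

The physical calibration (pinhole on a motorized stage behind a model
cornea, one exposure per Δz) is replaced by scalar wave optics:

* **Phase screen.** A Gaussian random field smoothed with a Gaussian kernel
  (periodic boundaries) and rescaled so the per-axis ray-deflection FWHM,
  θ = (λ/2π)|∇φ|, equals the diffuser's 0.5° divergence specification.
  Deterministic per (seed, parameters).
* **Correlation length: 60 μm default.** With the divergence fixed, the
  screen's RMS phase grows with the correlation length and the effective
  lenslet depth of field shrinks with it. The default is chosen so the
  caustic network is fully developed at the 11 mm diffuser–sensor distance
  with features of a few sensor pixels; much longer correlation lengths
  produce lenslets so weak that their depth of field spans the entire
  ±12 D calibration range, and the stack loses the defocus selectivity the
  instrument concept depends on. The real part's surface statistics are
  unpublished; only its divergence is matched.
* **Vergence relay.** Light from a fundus point reaches the cornea as a
  spherical wave of vergence 1/f_eye + ε/1000 (1/mm); relaying it through
  T(d_L3,D)·[[A, B], [C, D]] with the paraxial vergence transform
  V′ = (M₂₁ + M₂₂V)/(M₁₁ + M₁₂V) reproduces exactly the divergence from
  the conjugate fundus plane, 1/d_F″,D: ≈12.63 D for an emmetropic eye,
  11.0 D at −12 D, 14.25 D at +12 D. This beam vergence is what scales the
  caustic. `vergence_at_diffuser` returns the excess over the emmetropic
  baseline by default (0 at ε = 0, strictly monotone); PSF simulation uses
  the absolute value.
* **Propagation.** Band-limited angular spectrum over 11 mm at 550 nm (the
  green channel centre; spectral bandwidth is not simulated, and one stack
  serves all channels — the PSF is assumed achromatic). The field is
  limited by a soft super-Gaussian aperture, the conjugate-pupil patch on
  the diffuser; its default diameter is 0.6× the grid extent so desk-scale
  grids stay wraparound-free. Two vergence mechanisms are provided:
  `scale_mode='physical'` samples the quadratic phase explicitly (exact,
  but Nyquist-limited in grid × vergence, with a `SamplingError` naming
  the required sampling), and `scale_mode='geometric'` uses the Fresnel
  scaling theorem — propagate at z/(1 + zV), magnify by 1 + zV — which is
  alias-free at any grid size. The two agree on caustic RMS radius to
  better than 2 % and identically in ordering.
* The 20 μm physical calibration pinhole is treated as ideal (≈3 sensor
  pixels, below the caustic feature scale). PSFs are normalized to unit
  sum; whether the bench normalizes or background-subtracts measured PSFs
  is an instrument detail outside this simulator.

`mtf_radial` radially bins |FFT| of a unit-sum PSF; the noise-floor
resolution readout takes the highest sensor frequency with modulation
above the floor and maps it to the fundus via δ/R(ε). The floor default,
10⁻³ modulation, is a 16-bit-sensor heuristic and is configurable.

## Phantoms (`diffuscope.phantoms`)

The fundus phantom renders the gross structures a fundus camera sees —
reddish background with correlated choroidal texture, bright elliptical
optic disk, darker macula, a branching random-walk vessel tree of
decreasing caliber — with per-channel reflectances chosen so vessel
Michelson contrast orders green > red > blue (haemoglobin absorbs green
most strongly); full-depth vessel-core contrasts are ≈0.60/0.18/0.08. The
three-bar resolution target renders ordered groups of three dark bars on
bright ground with periods rounded to integer pixels; metadata records the
*realized* frequency, which is what every readout uses. Both generators
are pure functions of (seed, parameters). They emulate geometry and
contrast ordering only — not photorealistic reflectance spectra, pathology,
eye motion, or uneven illumination — so tests that pass on them demonstrate
algorithmic behaviour, not clinical image quality.

## Reconstruction (`diffuscope.recon`)

The forward model is convolution plus i.i.d. Gaussian noise; the inverse
is the closed-form Tikhonov filter (README). Numerical conventions:

* **PSF centre** at the geometric centre pixel (N//2, N//2), also for even
  sizes; `ifftshift` places it at the origin for the FFT.
* **Boundaries.** The Fourier solution is circulant. `pad_mode='linear'`
  (library default) zero-pads scene and measurement by the PSF support and
  crops back — appropriate for extended real scenes. `pad_mode='circular'`
  applies the literal periodic equation; it is the exact inverse of a
  periodic forward model, the form verified against a dense linear-algebra
  oracle, and the mode the synthetic demo uses end to end (phantom, blur
  and deconvolution share one FFT grid, so the periodic world is
  self-consistent and free of truncation artifacts that would otherwise
  dominate when the PSF is comparable in size to the desk-scale frame).
* μ = 0 (plain inverse filter) is refused unless min|H| > 1e−12.
* Per-channel μ defaults (0.007/0.002/0.02 for R/G/B) are the empirically
  balanced values for the three illumination channels; the NIR alignment
  channel shares the red setting and is displayed as red. Measurements are
  float throughout; 16-bit quantization is an optional simulation step.
* The reconstruction grid defaults to the stack's native ε grid; custom
  grids match stack planes by nearest neighbour within 0.05 D.

Color merging rescales each channel to [0, 1] by percentile clipping
(default 0.1–99.9 %, so at most ~0.2 % of pixels saturate per channel), or
sums channels for resolution targets where white balance is irrelevant.

## Autofocus and readout (`diffuscope.focus`)

Sharpness is the variance of the discrete Laplacian of the mean-normalized
image — scale-invariant by construction, zero for constant images; a
gradient-energy alternative is provided since no single metric is
canonical. Slices are scored after trimming a 10 % boundary margin (edge
artifacts from deconvolution would otherwise dominate), the argmax wins,
and ties break toward ε nearest zero. The reported confidence is the
best/median score ratio. At desk scale the sharpness peak across a focal
stack is shallow (ratios of order 1.01), and deconvolution of pure noise
can score *higher* than focused content because PSF-dependent noise
amplification varies systematically across the stack — so the
low-confidence warning threshold defaults off (1.0) and should be set
deliberately when used.

The bar-target readout averages the profile along the bars, computes
Michelson contrast, and calls a group resolved only if contrast reaches
the threshold (default 0.1, recorded in every readout) **and** all three
bars produce distinct local minima. The bench-to-eye correction multiplies
by f_model/f_eye = 25.4/16.7 ≈ 1.52.

## Problem sizes and reliability figures

The test suite runs desk-scale versions of the bench procedures; sizes
were chosen for seconds-scale runtimes while preserving the qualitative
regime:

* Autofocus reliability: 192-px grids, a 7-plane stack (Δz −12…+6 mm every
  3 mm), measurement noise σ = 10⁻³; 20 seeded captures at uniform random
  ε must land within one grid step of truth in ≥18 cases.
* Refocusing plateau vs fixed-PSF degradation: 1024-px grids, 30 μm screen
  correlation (finer features, larger aperture-to-feature ratio — the
  regime where PSF mismatch exceeds the matched resolution), μ = 10⁻⁴.
  The refocused readout varies by <35 % of its mean over −3…+12 D while
  fixed-0 D deconvolution degrades monotonically.
* Forward/inverse round trip: a 512-px scene with zeroed border, a 64-px
  PSF with a 0.15 mm pupil patch, μ = 10⁻⁴ → interior Pearson r ≥ 0.95.

These figures characterize the simulator, not a physical camera: real
measured PSFs, stray light, illumination nonuniformity and eye motion all
degrade a bench system in ways the simulation does not represent.

## Known limitations

Single wavelength per stack; exactly shift-invariant PSFs (the physical
system is only approximately LSI); single-scale Gaussian screen statistics;
no aberrations beyond defocus (no astigmatism or field curvature); no
iterative or learned reconstruction (closed-form Tikhonov only); FOV is a
paraxial upper bound. The confidence metric of the autofocus is a weak
indicator at desk scale (see above).
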