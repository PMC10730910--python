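# Methods

## Model overview

The package predicts the through-focus optical quality of a multifocal
refractive correction worn on an aberrated eye. Its inputs are (a) a
radial **sagittal power profile** of the lens — the local power, in
diopters, at each radial distance from the lens center, as produced by
phase-shifting Schlieren metrology at a nominal 28 samples/mm — and (b) a
per-eye table of OSA-indexed Zernike coefficients (µm) with the
measurement pupil diameter.

The computation proceeds in four stages:

1. **Segmentation.** The computation aperture of radius `R` is divided
   into `n` concentric annuli of equal radial width. Each annulus `l`
   receives the pure-defocus wavefront of its zone power `D_l`, evaluated
   over the full aperture and masked to the annulus; the disjoint pieces
   are summed into the lens wavefront `W_CL`. No piston matching is
   applied at zone boundaries — the inter-zone OPD steps are part of the
   model, since each zone genuinely focuses at a different distance.
2. **Superposition.** Ocular aberrations enter as a pupil-plane sum
   `W_T = W_CL + W_Eye` over `R = min(pupil radius, measured lens
   radius)`. The eye wavefront is synthesized from its coefficients over
   the eye's own measurement pupil and *cropped spatially* to `R`;
   coefficients are never rescaled to a different pupil, so they keep
   their measured meaning.
3. **Scoring.** The generalized pupil `P = A·exp(i2πW_T/λ)` yields the
   PSF and OTF by Fourier transform; the Visual Strehl ratio in the
   frequency domain weighs `|Re(OTF)|` by a neural contrast sensitivity
   function, normalized by the CSF-weighted diffraction-limited OTF of
   the same aperture, integrating over the frequency disk up to 60
   cycles/degree (the 20/10 acuity limit).
4. **Through focus.** Pure defocus emulating object vergence is added and
   the VSOTF swept over −1.00…+5.00 D in 193 samples. Curves are
   summarized by area under the curve, range above the 0.12 threshold,
   and peak performance, each optionally normalized by the same eye's
   monofocal reference.

Assumptions: monochromatic light, uniform pupil transmission (no
Stiles–Crawford apodization), radially symmetric lens zones (no angular
segmentation), a centered lens (no decentration or tilt), and a purely
neural CSF so that all optical degradation enters through the OTF.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `matrix_size` | 512 (128 in `--fast`) | px | canonical simulation matrix; 128² changes VSOTF by < 0.01 on the synthetic lenses (grid-convergence test) |
| `pupil_fill` | 0.25 | – | pupil diameter spans ¼ of the grid side: 4× zero-padding gives an alias-free OTF (support of the autocorrelation is twice the pupil) and frequency headroom beyond 60 cpd at all physiological pupils |
| `wavelength_nm` | 555 | nm | photopic luminosity peak; configurable |
| vergence grid | 193 samples on [−1, +5] D | D | step 6/192 = 0.03125 D; guarantees 0.00 D (index 32) is sampled |
| `threshold` | 0.12 | – | VSOTF level predicting 0.20 logMAR acuity |
| `freq_cutoff_cpd` | 60 | cpd | 20/10 visual acuity limit of the metric's integral |
| CSF | gain 2.6, floor 0.0192, scale 1/0.114 cpd, exponent 1.1 | – | band-limited `(a + f/fs)·exp(−(f/fs)^e)` family peaking near 8 cpd; the gain cancels in the VSOTF ratio, so only the shape matters. Defaults frozen in `RunConfig` for reproducibility |
| `n` zones | samples inside aperture | – | instrument-native: one annulus per measured radial sample; capped at 48 in `--fast` |

Sign conventions: positive sphere power maps to negative `c(2,0)`
(`c(2,0) = −P r²/(4√3)`, r the aperture radius, result in µm). The
through-focus axis is *added pupil defocus*; the clinical object-vergence
axis is its negative and is available as a presentation flag. Only
relative consistency of these signs affects the curves and metrics.

## Deliberate quirks kept as defined

* The per-sample dioptric weight of the range-above-threshold metric is
  **6/193 D although the grid spacing is 6/192 D**. Both constants are
  part of the metric's definition and are implemented literally; the
  ≈0.5 % mismatch is documented here rather than resolved.
* The VSOTF numerator uses `|Re(OTF)|` — the absolute value of the real
  part, not `Re` alone and not `|OTF|`.
* Samples exactly equal to the 0.12 threshold contribute nothing to the
  range metric (strict inequality).
* A single-zone (`n = 1`) segmentation is accepted and reduces exactly to
  a monofocal lens.

## Numerical choices

* **Annulus membership** is decided per pixel center: zone
  `l = floor(r·n/R)` for `r ≤ R`, clipped to `n−1`. This realizes
  half-open annuli `[R·l/n, R·(l+1)/n)` with ties at interior boundaries
  going to the outer zone and the outermost boundary closed, so the masks
  partition the pupil disk *exactly* — verified pixel-for-pixel in the
  tests for `n ∈ {1, 2, 7, 141}`.
* **Zone powers** take the mean of the profile samples falling inside the
  annulus; an annulus containing no sample (possible when the computation
  pupil is much smaller than the measured radius) falls back to linear
  interpolation of the profile at the annulus midpoint.
* **Grid geometry** is aperture-relative: the pupil always spans
  `pupil_fill` of the grid side, and the physical pitch scales with the
  aperture. This keeps frequency coverage identical across pupil sizes;
  physical support quantities must therefore be compared in mm, not
  pixels.
* **OTF computation**: PSF = |FFT(P)|², OTF = FFT(PSF) normalized to 1 at
  zero frequency — numerically identical to the pupil autocorrelation
  over its area (verified against a direct autocorrelation oracle to
  1e-8). Frequency calibration is one OTF sample per pupil-pixel shift,
  `Δf = (Δx/λ)·(π/180)` cycles/degree. The hot path evaluates the second
  transform on the real-FFT half-plane with multiplicity weights, valid
  because `|Re OTF|` is even in frequency.
* **Quadrature**: both VSOTF integrals are plain Cartesian sums over the
  grid frequencies inside the 60 cpd disk. The polar-coordinate Jacobian
  is omitted from *both* integrals, keeping the ratio self-consistent;
  the diffraction-limited denominator is computed through the identical
  FFT path with zero phase, so an unaberrated wavefront scores exactly 1.
* **Tie-breaks**: the curve maximum (and hence the equivalent-sphere
  shift) resolves ties toward the smallest |vergence|, then the smaller
  vergence.
* **Equivalent-sphere shift**: `shift = −argmax` of the monofocal curve;
  it is applied by evaluating every sample at `d − shift`, i.e. the
  optics carry the constant correction defocus `−shift`. This translates
  the curve by `+shift` so the monofocal peak lands on 0.00 D, and the
  same optical correction is reused for all lenses on that eye.
* **Discretization tolerances** asserted in the tests: single-mode RMS
  and orthonormality to 1 % on a dense 512² disk (3 % at 128²);
  diffraction-limited VSOTF to 1e-6 at 512², 1e-4 at 128².

## Synthetic data

The generator emulates the two study-scale inputs that real campaigns
obtain from proprietary sources.

**Lens profiles** (0–5 mm radius, 28 samples/mm, optional Gaussian
measurement noise, default SD 0.05 D in batch runs): constant
(monofocal); center-near and center-distance with a raised-cosine
transition (default boundary 1.5 mm, width 0.4 mm); aspheric with the
addition decaying quadratically from center to edge; and concentric
bifocal with alternating rings. The standard batch covers four families ×
three additions (0.75–2.75 D), each measured at base prescriptions
−6.00, −3.00 and +1.00 D (removed before analysis), plus one monofocal
control — 37 profiles in all.

**Eye populations**: pupil diameters uniform on 2.45–6.27 mm;
coefficient scales stated at a 6 mm reference pupil (order 2 astigmatism
0.15 µm, order 3: 0.12 µm, order 4: 0.05 µm, order 5: 0.02 µm, (6,0):
0.01 µm; spherical aberration mean +0.12 µm) and scaled to each eye's
pupil as `(r/3 mm)^n`, the leading power law of Zernike pupil dependence
— so small pupils carry proportionally small aberrations, as in real
populations. Defocus is drawn directly in diopters (residual equivalent
sphere of a distance-corrected eye, SD 0.3 D) and converted over the
eye's pupil. These magnitudes are order-of-magnitude realistic for
healthy adult eyes; the generator makes no attempt to reproduce any
specific population's covariance structure, inter-modal correlations, or
instrument noise. Passing tests therefore demonstrate the *method's*
correctness and stability across realistic magnitudes, not agreement
with any particular clinical dataset.

## Problem sizes

Unit and property tests run at 64²–128² with selected cross-checks at
256²/512². The batch-scale checks (2340 multifocal + 65 monofocal
curves) and the reproduction script use the 128² `--fast` profile with
zone counts capped at 48; the grid-convergence test bounds the effect of
this reduction on the VSOTF at 0.01.

## Known limitations

* Monochromatic only; no chromatic aberration, scattering or diffusion.
* No angular (non-radial) segmentation; astigmatic zone wavefronts are a
  natural extension of the per-zone wavefront but are not implemented.
* Lens decentration/tilt on eye is not modeled.
* Only the VSOTF metric is provided; other pupil- or image-plane metrics
  would plug in at the generalized-pupil stage.
* Absolute VSOTF values depend smoothly on the chosen CSF shape and
  wavelength; comparisons *between* lenses (normalized metrics) are far
  less sensitive to those choices than the raw values.
* Binocular combination and visual-acuity prediction beyond the fixed
  0.12 ↔ 0.20 logMAR mapping are out of scope.
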