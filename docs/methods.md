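# Methods

## Measurement model

The simulated instrument is a single-disperser CASSI camera. A scene
datacube f[k, y, x] (L bands on an (x, y) grid, arbitrary irradiance units)
is multiplied band-by-band by a binary coded mask T[y, x], each band is
displaced along +x by an integer pixel shift d_k, and the sensor integrates
the superposition:

    Y[m, n] = sum_k T[m, n - d_k] f[k, m, n - d_k] + g[m, n].

Assumptions baked into the operator:

- **Discrete box sampling.** The sensor's rect pixel-integration kernel is
  realized as discrete sampling on the camera grid with *integer* per-band
  shifts; there is no sub-pixel splatting. This matches a system whose
  smallest coded feature maps to a whole number (two) of camera pixels and
  whose bands are discretized one feature step apart, so every d_k is an
  integer by construction.
- **Dispersion along +x only**; the detector is max(d_k) columns wider than
  the scene so no band is cropped (zero padding elsewhere). Coordinates are
  0-based (band, row, column).
- **Additive Gaussian noise.** The sensor noise term g is i.i.d. zero-mean
  Gaussian with configurable sigma. Shot (Poisson) noise is a documented
  extension hook, not implemented.
- The operator accepts negative voxel values (ADMM iterates need them);
  only phantom constructors enforce physical non-negativity.

Because T is binary and the shifts are distinct, Phi Phi^T is exactly
diagonal; `gram_diagonal` returns its diagonal as a detector-shaped count of
open shifted mask copies. This is load-bearing for the reconstructor: every
cube-sized linear solve reduces to one elementwise division on the detector
grid.

## Dispersion calibration and band grid

The prism's nonlinear dispersion is represented piecewise-linearly: ordered
segments (lambda_start, lambda_end, nm_per_pixel). The pixel shift of a
wavelength integrates 1/(nm/pixel) from the reference wavelength (445 nm,
the shortest calibrated wavelength; any constant offset is a detector
placement choice). The packaged default covers 445-602 nm in four measured
segments (1.67, 2.00, 2.50, 3.33 nm/pixel). No extrapolation is allowed in
the public shift operation; physical prism models (Sellmeier) are out of
scope.

`discretize_bands` places band centers exactly one coded feature
(feature_px, default 2 pixels) of dispersion apart, giving shifts
d_k = k * feature_px and L = ceil(total_dispersion / feature_px) bands — 35
over the full default range. Band edges sit half a feature step either side
of each center, mapped back through the inverse dispersion; the two
outermost edges extrapolate the boundary segment's slope by half a step so
that every center lies strictly inside its edge pair.

## Reconstruction

The inverse problem min_f Psi(f) subject to y = Phi f (noise handled by the
penalty weight) is solved by an augmented-Lagrangian ADMM with splitting
f = v. Per iteration, in this order:

1. denoise: v = prox_{Psi/gamma2}(f - lam2/gamma2);
2. projection: the exact one-shot solve of
   f = (gamma2 I + gamma1 Phi^T Phi)^{-1}(lam2 + gamma2 v + Phi^T(gamma1 y - lam1))
   via the matrix-inversion lemma and the diagonal Gram;
3. multipliers: lam1 -= gamma1 (y - Phi f), lam2 -= gamma2 (f - v), both
   using the just-updated f and v.

Design choices where the design was genuinely open:

- **Denoiser contract instead of a learned prior.** The deep-unfolding
  variant of this architecture replaces the prox with a trained spectral
  transformer and learns the penalties; here the unfolded structure is kept
  but the prior is a classical, pluggable prox: `tv` (default), `identity`,
  or `external` (any callable honoring the prox contract). The guidance
  features such a learned denoiser would be conditioned on — the constant
  gamma2 map, the L shifted mask copies (a dense view of Phi), and the
  per-pixel Gram diagonal standing in for trace(Phi Phi^T), which is read
  here as the diagonal *map* rather than its scalar sum — are assembled by
  `guidance_features` and passed through untouched.
- **TV flavor.** Anisotropic (l1 of forward differences),
  channel-independent spatial TV; gradients along the band axis are a
  config option (`spectral=True`), off by default. The prox is solved by
  projected gradient on the dual with step 1/(4 * n_dirs * tau), within the
  ||D D^T|| <= 4 * n_dirs bound, for `max_inner_iters` (default 40)
  iterations; tau = strength/gamma2. A zero strength or a spatially
  constant input returns the input exactly.
- **Penalties.** gamma1 = gamma2 = 1 by default with an optional geometric
  per-iteration multiplier (`schedule`); the default prior weight
  strength = 0.2 sits on the flat optimum of a strength/penalty grid over
  seeded phantom instances. The trained-penalty route is out of scope.
- **Iteration policy.** Fixed n_iters (default 50), no tolerance-based
  early exit; a non-finite iterate raises a numeric error naming the
  iteration. Non-negativity is clamped only after the final iteration —
  clamping inside the loop would invalidate the closed-form projection
  algebra.
- Per-iteration diagnostics record ||y - Phi f||_2 and ||f - v||_2.

## Phantoms (what the generator emulates, and what it does not)

All phantoms are non-negative, seeded, and bit-reproducible.

- **rainbow_letter** emulates a letter object illuminated through a linear
  variable filter: each column carries a Gaussian passband (FWHM default
  12 nm, configurable across the filter's 7-20 nm range) whose center sweeps
  linearly across the wavelength range; per-pixel spectra are normalized so
  every glyph pixel integrates to the configured intensity.
- **usaf** renders three-bar chart elements at exact chart geometry (bar
  length = 5x width, gaps = one width), spectrally flat (broadband
  illumination), with bar width = period/2/um_per_pixel rounded to whole
  pixels (sub-pixel bars raise a resolution error). The rendering is ideal
  (contrast 1); optical blur is applied by the measurement chain or by the
  metrology tests, not by the chart.
- **eye** emulates a model eye with a vasculature-like pattern painted on
  its back surface: a smooth reflectance envelope (blurred noise, +/-15%)
  times a flat background spectrum, with seeded random branching curves
  carrying a smooth synthetic absorber peaking mid-band (paint, not
  hemoglobin — the package stays download-free). Defaults: 3 vessels of
  3 px base width tapering toward the tip, about 10% field coverage —
  a handful of major vessels scaled to the 32-64 px emulation fields used
  in tests. The vessel map is rendered band-limited (1 px Gaussian,
  `vessel_blur_px`) because the relay optics pass no detail below the
  two-pixel coded-feature resolution; an aliased binary curve would carry
  sub-resolution structure no optical image contains. The field-averaged
  spectrum of the cube is an exact coverage-weighted mix of the background
  and vessel spectra and serves as reconstruction ground truth.

What passing on these phantoms does **not** show: performance on real
fundus data (ocular aberrations, illumination vignetting, motion,
calibration drift, mask-alignment error are all absent), nor the
reconstruction quality of a trained denoiser.

## Metrology conventions

- USAF frequency 2^(group + (element-1)/6) lp/mm; period 1000/f um.
- Contrast is Michelson; a profile that is entirely zero has undefined
  contrast (error). Resolvability threshold 0.4, with ties counting as
  resolvable (the threshold sentence states no tie rule; >= is the
  generous reading).
- Spectral resolution = feature_px x nm_per_pixel; the bandwidth-weighted
  mean over the calibrated table is the headline average (the unweighted
  mean rounds to the same integer).
- **Reported values truncate toward zero at one decimal** (17.543 -> 17.5,
  15.625 -> 15.6, 6.66 -> 6.6). Truncation, not half-up rounding, is the
  convention the calibrated table is printed with (half-up would turn
  2 x 3.33 into 6.7).

## Problem sizes and numerical tolerances

Tests and the acceptance script run at desk scale: dense-oracle
equivalences on instances up to 12x12x4 (forward/adjoint/projection within
1e-8 absolute; Gram off-diagonals exactly zero), the adjoint identity to
1e-10 relative on 20 seeded 8x8 instances, and recovery experiments at
32x32x8 with 50 ADMM iterations (about a second each); the CLI integration
test uses 64x64x8. These sizes exercise every code path of the matrix-free
operator, whose cost is linear in voxels, so behavior at megapixel scale
differs only in runtime.

## Known limitations

- With the classical TV prior at 8:1 snapshot compression and a 50% open
  aperture, the converged reconstruction is data-consistent with total
  variation at or below the ground truth's — i.e. for scenes with
  appreciable fine structure the truth is not the TV-regularized optimum,
  and recovery accuracy is prior-limited rather than solver-limited. The
  headline PSNR figures written by `scripts/acceptance.py` quantify this
  ceiling for the vessel phantom; markedly higher fidelity at this
  compression requires a learned prior, which is deliberately outside this
  package's scope (the `external` denoiser hook is the integration point).
- Chromatic PSF blur, lens aberrations, and relay magnification chains are
  not modeled; the mask is assumed perfectly registered.
- Gaussian noise only; no Poisson/shot-noise model.
- The dispersion model is calibration-table-driven; it cannot extrapolate
  outside the calibrated range.
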