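# Methods

This note documents the models, numerical choices and limitations of
`synthrr`: what is simulated, how the algorithms are implemented, and
what the package's validation does and does not establish.

## Reconstruction model

All four algorithms — MLEM, MLEM+PSF, Richardson–Lucy (RL), and the
synthesized reconstruction — are instances of one multiplicative
expectation-maximisation update for independent Poisson data
`d ~ Poisson(Hθ)`:

    θ ← θ / (Hᵀ1) · Hᵀ( d / Hθ )

They differ only in the operator `H` and the data `d` (see the table in
`reconstruction.py`).  The update preserves nonnegativity and
monotonically non-decreases the Poisson log-likelihood of its own data;
both properties are asserted by the test suite rather than assumed.

The synthesized method frames post-reconstruction resolution recovery as
a fresh tomographic inverse problem: the input image θ⁽ᴷ⁾ (an existing
reconstruction whose resolution losses were never modelled) is forward
projected through a user-chosen virtual scanner `S` to give noiseless
synthetic data `m_syn = S θ⁽ᴷ⁾`, which are by construction consistent
with the virtual system model; reconstruction of `m_syn` with the
positron-range kernel `P` inside the model (`H = SP`) then recovers
resolution while the tomographic operator spreads — and thereby damps —
the noise that image-space RL deconvolution (`H = P`) amplifies locally.

## Projectors

The parallel-beam projector is a pixel-driven discrete Radon transform,
materialised once per (geometry, grid) pair as a sparse matrix: each
pixel centre is mapped to its signed radial coordinate
`s = x·cosφ + y·sinφ` and split between the two neighbouring radial bins
with linear-interpolation weights, scaled by the pixel size so sinogram
values approximate line integrals in mm.  Back projection is the exact
transpose of the same matrix.  A *matched* pair was a deliberate
requirement — the EM convergence and count-preservation properties
assume it — and is verified against dense-matrix oracles to 1e-6.

Conventions: rotation centre at the image centre; angles in degrees in
(0°, 180°], default 1°..180° in 1° steps ("native sampling"); radial bin
pitch equal to the pixel size; an odd bin count chosen to cover the
image diagonal.  The optional line-thickness parameter σ (in pixels)
widens the line integrals by blurring the image with an isotropic
Gaussian before projection; its adjoint applies the same symmetric blur
after back projection, so the matched-pair property survives.  A
geometry can also be declared the identity operator (sinogram ≡ image),
which turns the synthesized update into RL exactly and serves as an
algebraic cross-check.

## PSF kernels

Positron range is modelled in image space by a shift-invariant
convolution kernel with unit DC gain:

- **Gaussian**, parametrised by FWHM in mm (σ = FWHM / 2√(2 ln 2)),
  sampled at pixel centres, truncated at ±4σ and renormalised.  Default
  2.9 mm FWHM, the standard gallium-68 positron-range surrogate.
- **Monoexponential**, weights ∝ exp(−μr) with μ in mm⁻¹ on the 2-D
  pixel radius, truncated at 8 mm and renormalised.  Default
  μ = 0.77 mm⁻¹ (gallium-68 in high-resolution PET).  Defining the
  profile directly on the 2-D radius is a deliberate simplification of
  a 3-D range distribution.

Convolution is zero-padded ("same" size): all phantoms have empty
borders, and zero padding — unlike the circular wrap-around a circulant
matrix would imply — neither aliases activity across the field of view
nor breaks the exact adjoint relationship with the transposed kernel.
Kernels are sampled at pixel centres without area integration, adequate
at the default pitches; the FWHM measurement utility densifies the
profile with a cubic spline before locating half-maximum crossings,
because plain linear interpolation between 1 mm samples misreads a
2.9 mm FWHM by ~2.4%.

## Simulated data

Acquisitions follow a three-step protocol: blur the ground truth with
the PSF, forward project (native sampling), and draw independent Poisson
counts per bin after scaling the noiseless mean so its expected total
equals the count level.  No attenuation, scatter, randoms or detector
normalisation are simulated.  Count levels default to 1e7 / 1e6 / 1e5
expected total counts (high / mid / low) for a 128×128 phantom at 180
angles, spanning near-noiseless reconstruction down to ~3 counts per
bin where post-reconstruction deconvolution degrades sharply.
Realization q of a Q-realization set uses seed `base_seed + q`, making
every experiment bit-reproducible from its manifest.

Because reconstructions live on the count scale of the data, evaluation
scales the ground truth by the same global count factor before computing
metrics (the metrics are invariant to any *joint* rescaling, so this is
a bookkeeping choice, not a tuning knob).

## Phantoms

All validation objects are procedural: the high-contrast Shepp–Logan
head slice (classical signed-ellipse table, documented in
`phantoms.py`); a Derenzo-style resolution phantom with six 60° sectors
of hexagonally packed rods (diameters 1.1–4.7 mm, centre spacing twice
the diameter, rod:background activity 4:1); and a thorax-like slice —
body ellipse, two low-activity lungs, and a hot circular feature — that
stands in for an anatomical voxel phantom.  The stand-in preserves the
features the evaluation needs (a 70-pixel medium ROI inside the hot
feature, a 6-pixel small ROI adjacent to it, lungs, background) without
any external data download; it makes no claim to anatomical accuracy.
Default grids are 128×128 at 1 mm for Shepp–Logan and thorax, 240×240 at
0.25 mm for the Derenzo rods (1.1 mm rods need sub-millimetre sampling).

What the synthetic data do *not* emulate: attenuation and scatter,
detector blur, spatially variant or tissue-dependent positron range,
3-D geometry, and anatomical texture.  Passing tests therefore establish
the methods' relative behaviour under idealised 2-D Poisson conditions,
not absolute performance on real scanners.

## Evaluation metrics

At iteration k, over an ROI Ω with Q realizations: bias is the
normalised distance between the across-realization mean image and the
truth; the standard deviation term uses the 1/Q (population) convention
with deviations about that same mean; RMSE = √(bias² + stddev²), all
reported as percentages of the truth's root energy on Ω.  RMSE is never
stored independently of its components, so the Pythagorean identity
holds structurally.  Q defaults to 10 for the global and medium ROIs
and 100 for the small ROI.  `min_rmse` returns the earliest iteration
attaining the minimum (ties break to the smallest iteration).

## Numerical choices

- Division guards: EM denominators are clamped below at
  `epsilon × max(denominator)` per realization, `epsilon = 1e-12`;
  ratio entries with zero data are set to zero (their exact limit).
- Pixels with zero sensitivity are frozen at zero.
- Default initial image: uniform ones inside the reconstruction circle
  for the projector-based methods (MLEM convention; the synthesized
  method follows it too, configurable via `initial_image`), and the
  input image itself for RL.
- No implicit stopping rule: the iteration budget defaults to 500 with
  metrics recorded at every iteration; minima are found post hoc.
- Sensitivity images and system matrices are cached per
  (geometry, grid, kernel); caching is observationally transparent.
- Batched execution: the Q realizations of a study are iterated as one
  stacked EM run, with bias/stddev/RMSE streamed per iteration instead
  of storing Q×500 iterates.

## Study drivers and problem sizes

`run_method_comparison` evaluates the five methods (MLEM, MLEM+PSF, RL,
synthesized with PSF, synthesized without PSF) per count level and ROI,
with snapshot images at the global min-RMSE iteration and at the
standard 64-iteration point.  The hyperparameter sweeps vary the
virtual-geometry angle count, the line-thickness σ (the same σ-blur is
part of the virtual model during reconstruction, so the introduced blur
is recovered), and the input-image iteration count K (default 64, a
typical clinical software setting).

The package's own validation runs the headline low-count Shepp–Logan
comparison at full scale (128×128, 180 angles, Q = 10, ≤500 iterations),
and the four hyperparameter trend checks on a 64×64 thorax at 2.5e4
expected counts — the low-count default scaled by the pixel-count ratio
so counts per resolution element are preserved — with a 300-iteration
budget.

## Known limitations

- 2-D only; fan-beam, cylindrical 3-D geometries and time-of-flight are
  out of scope, as are regularised or ordered-subset variants.
- The absolute count levels of acquisition regimes are a modelling
  choice; comparisons across publications depend on them.  On this
  artifact's defaults, the low-count regime places even the reference
  standard (MLEM+PSF) near 46% global RMSE on Shepp–Logan, while the
  mid regime reproduces the ~33–35% floor; the *orderings* among
  methods are stable across regimes.
- RL's attainable minimum is bounded by the quality of the supplied
  input image; with very noisy inputs its best iterate is essentially
  the first.
- The monoexponential kernel is a 2-D reduction of a 3-D range
  distribution; spatially variant, tissue-specific kernels are not
  modelled.
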