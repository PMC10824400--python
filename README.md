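# synthrr — synthesized image reconstruction for PET resolution recovery

`synthrr` implements a post-reconstruction resolution-recovery (RR) method
for positron emission tomography: take an already-reconstructed image (for
example the MLEM output of a scanner's standard software), forward project
it through a **virtual scanner** to synthesise sinogram data, and then
re-reconstruct those synthetic data **with a point-spread-function model
inside the system model**.  The package is aimed at researchers in PET
image reconstruction and quantitative imaging who want resolution recovery
— especially for long-positron-range isotopes such as gallium-68 — without
access to scanner-specific projectors or raw sinogram data.

Alongside the synthesized method, the package provides its natural
comparators and a complete 2-D simulation and evaluation framework:
digital phantoms, Poisson sinogram simulation, MLEM and MLEM+PSF
reconstruction, Richardson–Lucy deconvolution, and bias/variance/RMSE
evaluation over noise realizations.

## The algorithms

All methods are multiplicative EM updates for a Poisson model.  With
system matrix `X`, PSF convolution matrix `P`, measured sinogram `m` and
image iterate θ:

- **MLEM**:  θ ← θ / (Xᵀ1) · Xᵀ( m / Xθ )
- **MLEM+PSF** (reference standard):  θ ← θ / (PᵀXᵀ1) · PᵀXᵀ( m / XPθ )
- **Richardson–Lucy** (post-reconstruction, input image θ⁽ᴷ⁾):
  θ ← θ / (Pᵀ1) · Pᵀ( θ⁽ᴷ⁾ / Pθ )
- **Synthesized reconstruction** (this package's namesake): synthesise
  `m_syn = S θ⁽ᴷ⁾` with a virtual scanner `S`, then
  θ ← θ / (PᵀSᵀ1) · PᵀSᵀ( m_syn / SPθ )

With `S = I` the synthesized update collapses to Richardson–Lucy, and
without `P` it collapses to MLEM on `m_syn` — identities the test suite
exploits as algebraic oracles.  The practical appeal of the synthesized
method is that it needs only an image and a PSF kernel, yet behaves like
PSF-in-the-loop reconstruction: the tomographic operator damps the noise
amplification that makes Richardson–Lucy degrade quickly on low-count
data.

PSF kernels model positron-range blur in image space: an isotropic
Gaussian parametrised by its FWHM in mm (2.9 mm is the usual gallium-68
surrogate) or a monoexponential `exp(-μr)` with attenuation coefficient μ
in mm⁻¹ (0.77 mm⁻¹ for gallium-68 in high-resolution PET).

## Worked example

Simulate a low-count acquisition of the Shepp–Logan phantom, reconstruct
an input image with 64 MLEM iterations, then apply the synthesized method:

```python
import synthrr as srr

truth = srr.make_shepp_logan(128, 1.0)                    # 128x128, 1 mm pixels
psf = srr.gaussian_kernel(2.9, 1.0)                       # 2.9 mm FWHM positron range
geometry = srr.ProjectionGeometry.native(128, 1.0, 180)   # angles 1..180 deg

sino = srr.simulate_acquisition(truth, psf, geometry,
                                srr.COUNT_LEVELS["low"], seed=1)
print("simulated counts:", int(sino.total_counts))

mlem_input = srr.mlem(sino, geometry, grid_size=128, n_iterations=64)
model = srr.SynthesizedReconstruction(mlem_input.final_image, geometry, psf)
result = model.fit(n_iterations=200, record_every=50)
print(result.summary())
```

which prints

```
simulated counts: 100173
SynthesizedReconstruction reconstruction results
============================================
iterations:        200
image grid:        128 x 128 (1.0 mm/pixel)
total activity:    556.523
data total:        100173
final loglik:      68315.9
recorded iterates: [50, 100, 150, 200]
```

The simulated sinogram carries ~1e5 counts (the default "low" level); the
reconstruction conserves the data total (total activity × 180 angles ≈
data total, a property of matched EM projectors), the Poisson
log-likelihood of the synthetic data is tracked per iteration, and
intermediate iterates are kept for metric curves.  Feeding Q = 10 such
realizations into `synthrr.compute_metrics` (or the one-call driver
`synthrr.run_method_comparison`) yields per-iteration bias, standard
deviation and normalised RMSE in percent, and `synthrr.min_rmse` locates
each method's best iteration.

The same studies run from the command line:

```sh
synthrr phantom --name shepp-logan --grid 128 --pixel-mm 1 --out truth.nii
synthrr simulate --phantom shepp-logan --counts low --q 10 --seed 1 --out sims/
synthrr recon --algo synth --input-image input.nii --psf-fwhm 2.9 --iters 500 --out recon/
synthrr run --config study.yaml            # full method comparison from a YAML config
```

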