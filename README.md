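# sbsd — sparse blind spherical deconvolution of diffusion MRI

Spherical-deconvolution methods for diffusion-weighted MRI (CSD, MSMT-CSD)
estimate the fiber orientation distribution in each voxel by deconvolving the
measured shell signal with a *response function* — the signal of a single
coherent fiber bundle — that must be estimated beforehand and is assumed
identical everywhere. `sbsd` implements a *blind* alternative that assumes
only the **axial symmetry** of each bundle's response: it recovers both the
crossing-fascicle orientations and a separate axially symmetric impulse
response per fascicle per voxel, with no explicit response function at all.

## The model

A signal `C` that is axially symmetric about the z-axis and antipodally
symmetric has the zonal expansion `C(ω) = Σₙ Cₙ⁰ Yₙ⁰(ω)` over even-degree
complex spherical harmonics. Rotating it so that its axis points along a unit
vector **u** multiplies each degree-n coefficient block by a **rotation
filter**, a unit-norm complex vector depending only on **u**:

    Cᵤⁿ = Cₙ⁰ · Uᵤⁿ,     Uᵤⁿ[m] = αₙ · conj(Yₙᵐ(u)),   αₙ = √(4π/(2n+1)).

A voxel containing K crossing fascicles is modeled as a linear mixture of K
rotated axially symmetric signals, so at every even degree n

    Sⁿ = Σₖ νₖ Cₖ,ₙ⁰ · U_{uₖ}ⁿ ,

where νₖ are the mix fractions (Σνₖ = 1). The algorithm has two independent
stages:

1. **Orientation retrieval** — at a single matching degree n₀, the measured
   coefficient block S^{n₀} is decomposed by complex orthogonal matching
   pursuit (OMP) over a precomputed dictionary of rotation filters on a fine
   hemisphere grid (4000 directions by default). The filters are nearly
   uncorrelated: `⟨Uᵤⁿ, Uᵥⁿ⟩ = Pₙ(u·v)` decays quickly with the angle between
   directions.
2. **Impulse-response recovery** — given any direction estimates (stage 1's,
   or peaks from an external tool), the real products `νₖCₖ,ₙ⁰` are recovered
   for every degree n ≥ 2 independently by Laplace–Beltrami-regularized least
   squares, `min ‖Sⁿ − Σₖ xₖU_{vₖ}ⁿ‖² + λ(n(n+1))²‖x‖²` (λ = 10⁻⁴). The
   degree-0 coefficient is not identifiable from a mixture; it is set per
   fascicle so the reconstructed axial profile is non-negative with minimum
   zero.

The package also ships a synthetic crossing-fiber phantom generator (analytic
stick+zeppelin kernel bank over a 5×5×2 grid of intra-/extra-axonal
diffusivities and volume fractions, Rician noise defined against the b=0
amplitude), the evaluation metrics (folded angular error with optimal
assignment, accuracy at the 10° threshold, normalized impulse MAE, and a
per-fascicle anisotropy index from a tensor fitted to each impulse), readers
and writers for NIfTI + FSL bvals/bvecs, and a command-line interface.

## Worked example

```python
import numpy as np
from sbsd import SparseBlindDeconvolution, default_kernel_bank, make_scheme, sample_crossing
from sbsd.metrics import angular_error

scheme = make_scheme(130, 3000.0, seed=1)        # electrostatic 130-direction shell
bank = default_kernel_bank()                     # 50 canonical kernels
voxel = sample_crossing(bank, scheme, snr=30.0, seed=12)

model = SparseBlindDeconvolution(voxel.noisy, scheme, n0=6)
res = model.fit(K=2)
print(res.summary())
errs = angular_error(res.directions[0], voxel.gt_directions).errors
print(f"angular errors vs ground truth: {errs[0]:.2f} deg, {errs[1]:.2f} deg")
print(f"per-fascicle anisotropy index: {np.round(res.anisotropy_indices(), 3)}")
```

prints

```
Sparse Blind Spherical Deconvolution Results
====================================================
shell b-value:       3000 s/mm^2 (130 directions)
SH order:            8   (lambda_lb=0.006)
matching degree n0:  6   (dictionary 4000 atoms)
fascicles (K):       2
stage-1 rel. residual at n0: 0.2596

fascicle          direction (x, y, z)  |nu C_n0|
       1 (+0.7265, +0.5011, +0.4701)      0.0623
       2 (-0.7496, +0.5916, +0.2969)      0.0397

nu_k C_k,n^0       n=0       n=2       n=4       n=6       n=8
  fascicle 1    0.5517   -0.4380    0.1967   -0.0513    0.0054
  fascicle 2    0.4335   -0.3410    0.1571   -0.0315    0.0072

angular errors vs ground truth: 1.55 deg, 1.54 deg
per-fascicle anisotropy index: [0.891 0.848]
```

Both crossing directions are recovered to ~1.5° at SNR 30, and the per-degree
coefficient rows are each fascicle's axial impulse response in the zonal SH
basis (negative n=2 coefficients: diffusion signals peak perpendicular to the
fiber). `res.impulse_profiles()` returns the responses on a z-grid and
`res.plot_profiles()` plots them.

The same pipeline is available from the shell:

```sh
sbsd simulate --bval 3000 --n-dirs 130 --snr 20 --n-samples 100 --seed 7 --out phantom/
sbsd fit-dirs --dwi phantom/dwi.nii.gz --bvals phantom/bvals --bvecs phantom/bvecs \
     --n0 6 --out peaks.nii.gz
sbsd fit-impulses --dwi phantom/dwi.nii.gz --bvals phantom/bvals --bvecs phantom/bvecs \
     --peaks peaks.nii.gz --out impulses.nii.gz
sbsd ai --coeffs impulses.nii.gz --peaks peaks.nii.gz --bval 3000 --out ai
sbsd experiment-a --n-samples 200 --seed 1 --out results/
```

## Coefficient layout

SH coefficients are complex, even degrees only, stored flat with degree
ascending and order m ascending from −n to n within each degree
(frozen by a golden test). Gradient directions are interpreted in the image
coordinate frame exactly as given in the bvecs table — no affine
re-orientation is applied.

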