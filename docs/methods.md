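# Methods

## Signal model and conventions

The package works with complex orthonormal spherical harmonics with the
Condon–Shortley phase, physics convention (θ colatitude, φ azimuth),
evaluated with `scipy.special.sph_harm_y`. Diffusion-weighted signals are
antipodally symmetric, so only even degrees are represented anywhere; the
flat coefficient layout is degree-ascending, order m ascending within each
degree. Coefficients are stored complex throughout; the conjugate symmetry
`c_{n,−m} = (−1)^m conj(c_{n,m})` of real-signal fits is asserted in tests
rather than exploited for storage, which keeps every linear-algebra step
generic and directly testable.

Rotating a zonal (axially symmetric) signal so its axis points along a unit
vector u multiplies each degree-n coefficient block by the rotation filter
`U_u^n[m] = α_n conj(Y_n^m(u))` with `α_n = sqrt(4π/(2n+1))`. This value of
α_n is the unique normalization for which the filters have unit l2 norm at
every direction (SH addition theorem) and for which the filter correlation
equals `P_n(u·v)`; both identities are enforced to 1e-10 in tests. Only this
(m, 0) column of the Wigner rotation matrices is ever needed, so no general
SO(3) machinery is used.

A K-fascicle voxel is modeled as `S^n = Σ_k ν_k C_{k,n}^0 U_{u_k}^n` at every
even degree: the mixture of K rotated axially symmetric responses, each with
its own coefficients. Only the products `ν_k C_{k,n}^0` are identifiable —
the mix fraction and the response amplitude cannot be separated from a single
voxel, and no attempt is made to do so.

## SH fitting

Expansions are estimated by penalized least squares with the
Laplace–Beltrami weight `λ_lb (n(n+1))²` per coefficient. Default
`λ_lb = 0.006`, the value conventionally used with this regularizer; the
degree-0 coefficient is unpenalized. Expansion order follows the shell:
8 for b ≤ 5000 s·mm⁻², 10 above (the higher shell needs more degrees to
represent the sharper signal). With λ_lb = 0 and a rank-deficient design the
fit raises an explicit error instead of silently regularizing. For repeated
fits on one scheme the solver (a penalized pseudoinverse) is precomputed
once and applied as a matrix product to whole sample batches.

Within one degree the penalty rescales signal and noise equally, so stage-1
direction estimates are insensitive to λ_lb; it matters for the stage-2
coefficient amplitudes and for the reconstructed profiles.

## Stage 1: orientation retrieval

The degree-n₀ block of the fitted expansion is decomposed by complex
orthogonal matching pursuit over a dictionary of rotation filters on a
hemisphere grid. Choices and their rationale:

- **Grid**: a deterministic Fibonacci-spiral hemisphere of 4000 directions
  (nearest-neighbor folded spacing ≤ 2.8°, verified in tests). A spiral is
  used rather than iterated electrostatic repulsion because at N = 4000 the
  repulsion adds O(N²) work per iteration for no measurable change in the
  nearest-neighbor statistics that control angular resolution.
- **Greedy step**: atoms are unit-norm, so the OMP selection is
  `argmax |⟨residual, atom⟩|` with no renormalization, followed by a joint
  complex least-squares re-projection over all selected atoms and a residual
  update.
- **Stopping**: fixed K supplied by the caller (K = 2 throughout the
  synthetic validation). An optional residual-ratio stop is available but
  off by default.
- **Exclusion**: after each pick, atoms within 15° of a selected direction
  are masked. The dictionary is coherent at low degree (`P_{n₀}(cos γ)`
  decays slowly), and without masking the second pick often lands on the
  first lobe again. The phantoms are generated with ≥ 25° separation, so
  masking at 15° cannot hide a true second fascicle. Configurable; 0
  disables.
- **No continuous refinement**: estimates are grid atoms. Refining off-grid
  would improve the numbers but make them incomparable with grid-based
  accuracy figures.

### Known limitation: greedy matching on a coherent dictionary

Single-degree matching has a genuine failure mode, measured and documented
rather than patched. For two fascicles with similar same-sign weights
`ν₁C₁` ≈ `ν₂C₂`, the correlation function `w₁P_n(v·u₁) + w₂P_n(v·u₂)` can
attain its maximum modulus at a *third* direction — near the angle where
P_n reaches its negative extremum (≈ 33° for n = 6, P₆ ≈ −0.41) from both
true axes — so the greedy first pick is wrong by tens of degrees, and OMP
never discards a picked atom. Even away from this regime the second
fascicle's contribution tilts the first argmax to a neighboring grid atom,
so noiseless "exact" recovery of snapped directions holds in only ~30–60% of
random cases (n₀ = 6 / 8), while recovery within the 10° accuracy threshold
reaches 92–98%. Noiseless accuracy therefore saturates near, not at, 100%.
The exhaustive pair-LS oracle (all grid pairs) does recover exactly — the
failure is the greedy heuristic, not the model — but at 4000² pairs it is
only practical as a test oracle.

## Stage 2: per-fascicle impulse responses

Given direction estimates, each even degree n ≥ 2 is solved independently:

    min_x ‖S^n − Σ_k x_k U_{v_k}^n‖² + λ (n(n+1))² ‖x‖²,   λ = 1e-4,

with x constrained real by stacking the real and imaginary parts of the
system (the unknowns are physically real; solving the complex problem and
taking the real part is not equivalent and is rejected). Degrees decouple
because the penalty and the unknowns are per-degree.

Degree 0 is not identifiable: any split of the voxel mean across fascicles
reproduces the signal, and the K = 1 system at degree 0 is scale-singular.
The zero-mean signal content (degrees ≥ 2) is fitted first, then each
fascicle's degree-0 coefficient is set to the opposite of the minimum of its
degree-≥2 axial profile (evaluated on a 401-point uniform z-grid; at least
201 points are required to locate the minimum), making the reconstructed
response non-negative with minimum zero.

Reconstructed profiles are degree-n_max polynomials in z while the true
kernels are exponential and peaked, so ringing near the poles (z = ±1) and a
systematic undershoot of the z = 0 peak are expected behaviors of the
truncation, not bugs; tests bound the noiseless profile error by twice the
quadrature-measured truncation error. Volume processing drops peaks below
0.1 × the voxel's largest peak norm, l2-normalizes the survivors, fits up to
K_max = 3 fascicles, and zero-fills voxels with no surviving peak.

## Synthetic phantoms

The generator emulates a two-fascicle crossing protocol: two canonical
kernels drawn uniformly from a 50-kernel bank, two directions uniform on the
sphere rejection-sampled to ≥ 25° folded separation, mix fraction ν₁ uniform
in [0.5, 0.85], and Rician noise `sqrt((s+σN₁)² + (σN₂)²)` with
σ = b0_signal/SNR (SNR defined against the b = 0 amplitude, so the effective
noise grows with b as the signal attenuates).

The canonical kernels are analytic stick+zeppelin two-compartment signals

    K(z) = fvf·exp(−B·D_in·z²) + (1−fvf)·exp(−B·D_ex·z²)·exp(−B·(1−fvf)·D_ex·(1−z²))

over the grid D_in ∈ {1.5, 2, 2.25, 2.5, 3}×10⁻⁹ m²s⁻¹,
D_ex ∈ {1, 1.5, 2, 2.5, 3}×10⁻⁹ m²s⁻¹, fvf ∈ {0.7, 0.8} (5×5×2 = 50
kernels), with the usual tortuosity coupling for the extra-axonal radial
diffusivity. An analytic bank stands in for Monte-Carlo substrate
simulations: it preserves the axial symmetry and unit b=0 amplitude the
algorithm relies on and the same parameter grid, but not the restricted,
non-Gaussian character of intra-cylinder diffusion — analytic kernels carry
somewhat less high-degree angular energy, so stage-1 accuracies at a given
SNR run a few points below figures obtained with Monte-Carlo substrates, and
the gap is largest at b = 10000 s·mm⁻². The SMT-style kernel
`exp(−Bλ∥z²)exp(−Bλ⊥(1−z²))` is also provided. Passing tests on these
phantoms validate the pipeline under exactly the sparse-mixture model; they
do not speak to fiber fanning, axonal tortuosity, exchange, or spatially
correlated noise in real data.

Acquisition schemes are antipodal point sets relaxed by electrostatic
(Coulomb) repulsion from a seeded random start — 1000 projected-gradient
iterations with linear step decay, deterministic per seed. b-values are
carried in s·mm⁻², diffusivities in m²·s⁻¹; the unit conversion
(1 s·mm⁻² = 10⁶ s·m⁻²) lives in a single audited function. Randomness flows
from one master seed; per-sample seeds are spawned from it so any sample is
reproducible in isolation.

## Metrics

Angular errors are folded (`arccos|û·v̂|` ∈ [0°, 90°]) and matched
one-to-one by minimal total error (exhaustive for ≤ 3 fascicles, Hungarian
beyond); unmatched true fascicles score 90°. Accuracy is the pooled fraction
of fascicles strictly below 10°. Impulse error is the mean absolute error
normalized by the mean of the ground-truth profile.

The anisotropy index applies the fractional-anisotropy eigenvalue formula
`sqrt(3/2)·sqrt(Σ(λᵢ−λ̄)²/Σλᵢ²)` to a tensor fitted log-linearly to the
impulse profile synthesized at the scheme directions (values clipped at
1e-6 × max before the log). Shell-only data cannot separate the reference
amplitude from the isotropic part of the tensor — (D, S0) and
(D + aI, S0·e^{Ba}) produce identical shell signals — so the fit takes an
explicit reference amplitude `s0` (default 1, the b0-normalized convention
used throughout) instead of a free intercept; eigenvalues and AI are exactly
covariant under joint rescaling of profile and s0.

## Validation experiment and problem sizes

`run_experience_a` sweeps (b-value × direction count × SNR × n₀), generating
a fresh phantom batch per condition and reporting stage-1 accuracy and mean
angular error plus the stage-2 normalized MAE at ground-truth directions.
The package's standard validation runs use 1000 samples per condition
(Monte-Carlo standard error on an accuracy of ~0.75 is then ≈ 0.01), with
the full grid available through the config. Measured behavior reproduces the
expected qualitative ordering: degree-8 matching is most accurate at high
SNR and high b-value, degree 4 is the most noise-robust, and accuracy
degrades monotonically as SNR drops at every degree.

## Degenerate inputs and numerical choices

- Zero-signal voxels and voxels with no surviving peak produce zero output
  and are counted in the log, not errors.
- OMP refuses a zero coefficient vector and reports how many atoms were
  found if exclusion masks the whole grid before K picks.
- Coincident (after folding) stage-2 directions are rejected; more fascicles
  than the 2n+1 equations at some degree triggers a warning (the ridge
  solution remains defined).
- Kernel quadrature projections use cached 2048-node Gauss–Legendre rules —
  far beyond the polynomial degree of any integrand here and verified
  against a 20000-node rule in tests.
- Antipodal folding maps directions to z > 0 with a deterministic
  tie-break on the equator.
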