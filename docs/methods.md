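# Methods

## Signal model

Each voxel is a mixture of compartments. A coherent white-matter (WM)
fiber population with orientation **d** contributes a mono-exponential
tensor signal

    S(b, v) = S0 · exp(−b vᵀ D v),   D = R A Rᵀ,  A = diag(λ1, λ2, λ3),

where R is the minimal (Rodrigues) rotation taking the x-axis onto
**d** (a fixed 180° rotation about z is used for the anti-parallel
degenerate case; any valid R gives the same quadratic form). Grey
matter and CSF contribute isotropic terms exp(−b·D_GM) and
exp(−b·D_CSF). Sampling the fiber orientation on a dense antipodally
symmetric grid of M directions turns the model into a linear system
S = H f with H of size N×(M+2): M rotated single-fiber columns plus the
two isotropic columns. The non-negative coefficient vector f is the
fiber orientation distribution function (fODF) on the grid.

Defaults (single-shell evaluation setting): λ1 = 1.7·10⁻³,
λ2 = λ3 = 0.3·10⁻³ mm²/s (a sharp response), isotropic diffusivities
0.1·10⁻³ and 2.5·10⁻³ mm²/s, S0 = 1, and a scheme of 70 gradient
directions at b = 3000 s/mm² plus one b = 0 image. The challenge-like
phantom generator instead uses GM/CSF diffusivities 0.2·10⁻³ and
1.7·10⁻³ mm²/s.

## Sphere grids

The fODF grid must be antipodally symmetric (diffusion is even in the
gradient direction) and near-uniform. Two constructions are provided:
exact icosahedral subdivision for M ∈ {12, 42, 162, 642, 2562}, and,
for any other even M, electrostatic repulsion of M/2 antipodal pairs
seeded from a Fibonacci spiral (250 fixed, deterministic descent
steps). The default M = 724 grid has a mean neighbor separation of
about 8.2° (SD 0.56°), recorded in the grid metadata as a diagnostic;
adjacency is the convex-hull triangulation. The separation statistics
matter because peak extraction and the "within one grid spacing"
angular-error interpretation are resolution-limited by them.

## Noise model and simulation

Each of n coils measures the true signal weighted by its sensitivity
map C_k plus complex Gaussian noise; real and imaginary parts are
independent draws across coils with compound-symmetric covariance
σ²[(1−ρ)I + ρ11ᵀ], sampled exactly through its Cholesky factor.
Magnitude images are formed either by root sum of squares
(SoS = √Σ|S_k|², noncentral-χ noise of order n) or by the spatial
matched filter (SMF = |Σ S_k C_k|, Rician noise when ΣC_k² = 1).
The nc-χ density is evaluated in log space with the exponentially
scaled Bessel function I_{n−1}, with the analytic central-χ limit
substituted where S̄·S/σ² < 10⁻¹²; non-integer orders are accepted so
that effective (n_eff, σ_eff²) parameters can be used for correlated
data. Simulation defaults mirror the evaluation design: n = 8 coils,
ρ = 0.05, SNR = S0/σ ∈ {10, 15, 20, 30}, and matched noise
realizations across combiners for a paired design.

Sensitivity maps are synthetic: one broad truncated-Gaussian lobe per
coil, centered on n equally spaced points of a circle of radius
0.6·max(shape) in the axial plane, width 0.6·max(shape), jointly
normalized so ΣC_k² = 1 voxelwise. The real coil geometry this stands
in for is unknown, so only the normalization constraint and the
"broad lobe per coil" qualitative shape are enforced. One consequence
worth knowing: with ρ > 0 the SMF-combined image has variance
σ²[(1−ρ) + ρ(ΣC_k)²] ≥ σ², and the broader (more mutually similar)
the maps, the closer (ΣC_k)² is to its maximum n. With the default
maps this inflates the SMF variance by ≈1.30× at ρ = 0.05, i.e. an
effective SNR of ≈13 when the nominal per-coil SNR is 15. The σ²
recovery checks therefore compare the solver's estimate against this
effective variance — the quantity the Rician likelihood actually
parameterizes — not against the nominal per-coil value.

## The Rician/nc-χ Richardson–Lucy solver

The solver maximizes the nc-χ likelihood of S = Hf by the
multiplicative fixed-point iteration

    f ← f ∘ Hᵀ[S ∘ r(S ∘ Hf/σ²)] / (HᵀHf),

where r(z) = I_n(z)/I_{n−1}(z) and n = 1 for Rician (SMF) data, n =
the coil count (or n_eff) for SoS data. Starting from a uniform
positive fODF, every iterate is non-negative by construction and no
matrix inversion is ever performed. The noise variance is re-estimated
each iteration, voxel by voxel, from the same data:

    α ← [ (SᵀS + ‖Hf‖²)/2 − Σᵢ (S ∘ Hf)ᵢ rᵢ ] / (nN),

floored at 10⁻¹⁴ to stay positive. The variance map is kept voxelwise
in all modes. Iteration count is the effective angular-regularization
parameter; the default 200 (400/600/1000 supported) follows the
evaluation design, and termination is by fixed count because a
residual-based stop would itself change the regularization. α° is
initialized at (0.1 · mean b=0 signal)²; the fixed point is
insensitive to this start.

The per-iteration log records the negative log-likelihood and the mean
variance estimate; the NLL is non-increasing in practice (asserted to
1e-8 relative tolerance in tests) even though the alternating
f/α scheme does not formally guarantee joint monotonicity.

### Bessel-function ratio

r(z) = I_ν(z)/I_{ν−1}(z) is computed as a single composite function via
Perron's continued fraction

    r(z) = z / (2ν + z − K_{k≥1} [ (2ν+2k+1) z / (2ν+k+2+2z) ]),

evaluated backward at fixed depth 48, which reproduces an
arbitrary-precision series oracle to ~1e-14 over z ∈ [10⁻⁶, 10⁶] and
orders 1–32, with no overflow at any argument (a naive quotient of
I_ν values overflows near z ≈ 700). The inner loop is JIT-compiled
with numba when available, with an identical pure-NumPy fallback.
Real orders ≥ 1 are supported for effective-parameter models.

### Total-variation regularization

The MAP variant multiplies the update by the per-channel factor
R_j = 1/(1 − α_TV div(∇f_j/|∇f_j|)), computed with forward-difference
gradients, their negative-adjoint backward-difference divergence and
replicate (Neumann) boundaries, so that div = −∇ᵀ. |∇f| is smoothed as
√(|∇f|² + ε) with ε = 10⁻¹⁰ (results are insensitive over
10⁻⁶…10⁻¹⁴); negative multipliers are replaced by their absolute value
to preserve non-negativity, and the denominator is floored at 10⁻⁶ in
magnitude. α_TV follows the discrepancy principle: the masked mean of
the variance map (`global`), the per-voxel map (`voxelwise`), or a
user-fixed constant (`tv_weight`); `none` disables the factor, and a
zero weight reproduces the unregularized update bitwise.

### Optional normalization

After each update f may be rescaled to unit sum, preserving the
reading of f_j as a volume fraction.
This is the default for the Rician/nc-χ solver and off by default for
the damped-RL baseline, matching each method's original formulation;
both are switchable.

## The damped Richardson–Lucy baseline

The Gaussian-noise baseline iterates
f ← f ∘ [1 + u ∘ (HᵀS/(HᵀHf) − 1)] with the geometric damping factor
u_j = r_j^ν/(r_j^ν + η^ν), r_j = f_j/max(f), ν = 8, η = 0.06. The
factor freezes components small relative to the voxel maximum,
suppressing the growth of spurious peaks; u → 1 (plain RL) as η → 0,
and `damping=None` gives the exact undamped recursion. Any f with
Hf = S is a fixed point regardless of damping. The TV factor can be
attached in the same way, with α_TV driven by the per-voxel Gaussian
residual variance ‖S − Hf‖²/N — the Gaussian analogue of the nc-χ
variance update, chosen because the original damped-RL formulation
does not prescribe a TV schedule.

## Peak extraction and metrics

Peaks are grid vertices whose WM weight is ≥ every triangulation
neighbor, deduplicated across antipodal pairs (keeping the
larger-valued member), thresholded at 0.1·f_max and capped at the four
largest, with mutually adjacent survivors suppressed in amplitude
order. Per voxel, the angular error is the mean over true fibers of
the minimum |angle| to any peak; the volume-fraction error compares
true fractions against peak amplitudes normalized to the voxel's
estimated total WM fraction (amplitude/Σamplitudes × f_WM), matching
each true fiber to its angularly closest peak with ties broken by
amplitude. The normalization choice is pinned by tests; the raw peak
amplitude is a density value on the grid and is not itself a volume
fraction, so some such rescaling is unavoidable. Voxels where no peak
survives the threshold are excluded from the angular/fraction means
and contribute to the under-detection count n⁻; the success rate is
the fraction of voxels whose detected count equals the true count.

## Phantoms

The crossing-angle family places two straight bundles in a cube: one
occupies the middle band in y, the other the middle band in z (band
half-width = shape/6), with fiber directions in the x-y plane at
±angle/2 about x. The overlap is the crossing region (fractions ½/½,
or (1−minor, minor) for the volume-fraction family at 70°); voxels in
one band only are single-fiber (fraction 1); everything else is
CSF-like isotropic background. This is the simplest geometry with a
well-defined crossing region, and it is scale-invariant: a 12³ phantom
has the same per-voxel truth structure as a 50³ one, only fewer voxels.
The challenge-like phantom adds a curved (arc) bundle whose truth
direction is the local tangent, a branching diagonal bundle, and a
CSF ball, with equal WM fractions where bundles overlap; its
intra-axonal physics is deliberately simplified to the same tensor
mixture as the other families, so it probes geometric complexity, not
microstructure. The full suite enumerates 90 + 41 + 1 = 132 specs.

What the generator does *not* emulate: restricted (non-Gaussian)
intra-axonal diffusion, axon-diameter effects, spatially varying S0,
susceptibility or motion artifacts, and k-space undersampling. Passing
the phantom tests therefore demonstrates correct recovery under the
generative model the solvers assume, plus realistic magnitude noise —
not robustness to model misspecification beyond the
diffusivity-mismatch experiments a user can run by varying the
dictionary profile.

## Problem sizes and numerical choices

The tests and the acceptance script run the full-fidelity model
(M = 724 grid, N = 71 scheme, 200 iterations, 8-coil noise) on reduced
12³ volumes — 1728 voxels instead of 125 000 — which preserves the
per-voxel statistics of the larger phantoms while keeping a single run
in the tens of seconds. Denominators in the multiplicative updates are
floored at 10⁻¹², the variance at 10⁻¹⁴, and likelihood arguments at
10⁻³⁰⁰ before logs; these guards only engage on degenerate voxels
(all-zero signal), which are excluded from the mask. Both solvers are
deterministic: the only randomness in the pipeline is the noise seed,
which is recorded in the provenance of every output.

## Known limitations

- The fODF is a discrete density on the grid; no spherical-harmonic
  continuous representation is provided.
- Effective noise parameters (n_eff, σ_eff²) are accepted as inputs but
  not estimated from raw data.
- The TV scheme is first-order and channel-by-channel; fiber-continuity
  or vectorial couplings between fODF channels are not modeled.
- Success rates at small crossing angles (≲ 20°) are limited by the
  grid resolution and by noise-driven lobe splitting; TV regularization
  mitigates but does not remove this.
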