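# rumbasd

Model-based spherical deconvolution of diffusion MRI data under
realistic magnitude-noise models — Rician (matched-filter coil
combination) and noncentral χ (sum-of-squares combination across n
coils) — with optional total-variation (TV) spatial regularization, a
damped Richardson–Lucy Gaussian-noise baseline, a multichannel-noise
phantom simulator, and fODF evaluation metrics.

It is written for diffusion-MRI methods researchers who want to
estimate intra-voxel fiber orientations from single-shell HARDI data
without pretending the noise is Gaussian, and to benchmark solvers on
synthetic phantoms with known ground truth.

## The model

Each voxel's signal is a mixture of oriented white-matter compartments
plus grey-matter and CSF terms:

    Sᵢ = S0 ( Σⱼ fⱼ exp(−bᵢ vᵢᵀ Dⱼ vᵢ) + f_GM exp(−bᵢ D_GM) + f_CSF exp(−bᵢ D_CSF) )

Sampling the fiber orientation on a dense antipodally symmetric sphere
grid (M = 724 by default) gives the linear system **S = H f**, where
the non-negative vector **f** is the fiber orientation distribution
function (fODF). The magnitude data follow a noncentral-χ law of order
n (n = 1 is Rician), so the solver iterates the multiplicative
maximum-likelihood update

    f ← f ∘ Hᵀ[ S ∘ Iₙ(S∘Hf/σ²)/Iₙ₋₁(S∘Hf/σ²) ] / (HᵀHf)

jointly with a per-voxel noise-variance update, starting from a
uniform fODF — non-negativity is preserved at every step and no matrix
is ever inverted. The Bessel-function ratio is evaluated as a single
composite function through Perron's continued fraction, so it is
stable at any SNR. A TV factor can multiply the update to couple
neighboring voxels, with its weight set automatically from the
estimated noise variance (discrepancy principle). The damped
Richardson–Lucy baseline (`drl_sd`, ν = 8, η = 0.06) provides the
Gaussian-noise reference the Rician/nc-χ solver is compared against.

## Worked example

```python
from rumbasd import RunConfig, run_experiment

config = RunConfig(
    family="crossing_angle", angle=70.0, shape=(12, 12, 12),
    snr=15.0, combiner="smf", method="rumba", noise_family="rician",
    iterations=200, seed=1,
)
report, result, phantom = run_experiment(config)
```

This generates a 12³ phantom with two fiber bundles crossing at 70°,
contaminates it with 8-coil correlated noise (ρ = 0.05) combined by the
spatial matched filter at SNR 15, deconvolves with the Rician solver
and scores the result against ground truth. Running
`python examples/fit_crossing_phantom.py` prints:

```
evaluated 960 fiber voxels (192 in the crossing region)
crossing angular error:    6.62 deg (grid spacing ~8.2 deg)
crossing fraction error:   0.088
crossing success rate:     0.781 (n+ 0.234, n- 0.000)
noise variance: estimated 0.00548 vs 0.00576 present in the combined data
```

The angular error (mean angle between each true fiber and its closest
detected fODF peak) is below the grid spacing; the success rate is the
fraction of crossing voxels where exactly two peaks are found, with
the over/under-detection split into n⁺/n⁻; and the jointly estimated
noise variance lands within 5% of the variance actually present in
the matched-filter image. `examples/tv_regularization_effect.py` shows
the effect of the TV prior on a hard 30° crossing (success rate 0.19 →
0.93), and the other examples cover dictionary construction and the
noise simulator.

## Command line

A thin CLI wraps the library:

```bash
rumbasd phantom  --family crossing --angle 70 --shape 50,50,50 --snr 15 --out ph/
rumbasd fit      --data ph/dwi.nii.gz --bvals ph/bvals --bvecs ph/bvecs \
                 --method rumba --noise rician --tv none --iters 200 --out fit/
rumbasd evaluate --fodf fit/fodf.nii.gz --grid 724 --truth ph/ --out report.json
rumbasd suite    --shape 12,12,12 --angles 30,50,70 --out suite.json
```

Volumes are NIfTI-1, gradient tables are FSL-style bval/bvec files,
reports and provenance are JSON.

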