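"""End to end: noisy crossing phantom -> fODF field -> recovery metrics.

Generates a reduced 12^3 phantom with two bundles crossing at 70
degrees, adds 8-coil SMF noise at SNR 15, deconvolves with the
Rician-likelihood solver (200 iterations) and scores the result against
the stored ground truth.
"""

from rumbasd import RunConfig, run_experiment

config = RunConfig(
    family="crossing_angle", angle=70.0, shape=(12, 12, 12),
    snr=15.0, combiner="smf", method="rumba", noise_family="rician",
    tv_mode="none", iterations=200, seed=1,
)
report, result, phantom = run_experiment(config)

d = report.to_dict()
cross = d["crossing"]
print(f"evaluated {d['n_voxels']} fiber voxels "
      f"({cross['n_voxels']} in the crossing region)")
print(f"crossing angular error:    {cross['theta_mean_deg']:.2f} deg "
      f"(grid spacing ~8.2 deg)")
print(f"crossing fraction error:   {cross['df_mean']:.3f}")
print(f"crossing success rate:     {cross['success_rate']:.3f} "
      f"(n+ {cross['n_plus']:.3f}, n- {cross['n_minus']:.3f})")
print(f"noise variance: estimated {d['sigma2_estimated']:.5f} vs "
      f"{d['sigma2_true_effective']:.5f} present in the combined data")
print("the angular error is the mean angle between each true fiber and its "
      "closest detected fODF peak; the success rate is the fraction of "
      "voxels with exactly two detected peaks")
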