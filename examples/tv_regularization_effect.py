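"""Effect of total-variation regularization on a hard crossing.

Runs the Rician solver with and without the TV spatial prior on a
30-degree crossing at SNR 15 — an angle near the resolution limit —
and compares success rates and angular errors.  TV couples neighboring
voxels, suppressing noise-driven spurious peaks while preserving the
bundle boundaries.
"""

from rumbasd import RunConfig, run_experiment

for tv_mode in ("none", "global"):
    config = RunConfig(
        family="crossing_angle", angle=30.0, shape=(12, 12, 12),
        snr=15.0, method="rumba", noise_family="rician",
        tv_mode=tv_mode, iterations=200, seed=7,
    )
    report, _, _ = run_experiment(config)
    cross = report.to_dict()["crossing"]
    label = "RUMBA-SD" + ("+TV" if tv_mode != "none" else "   ")
    print(f"{label}: success rate {cross['success_rate']:.3f}, "
          f"angular error {cross['theta_mean_deg']:.2f} deg, "
          f"n+ {cross['n_plus']:.3f}, n- {cross['n_minus']:.3f}")
print("the TV prior adapts its weight to the estimated noise variance "
      "(discrepancy principle), so no regularization parameter is hand-tuned")
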