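"""Contaminate a noiseless phantom with realistic multichannel MRI noise.

Eight coils with correlated complex Gaussian noise (rho = 0.05) are
combined with the two standard strategies: root sum of squares (SoS,
noncentral-chi magnitude noise) and spatial matched filter (SMF, Rician
magnitude noise).  The same seed reuses the same complex noise draws,
so the two volumes form a matched pair.
"""

import numpy as np

from rumbasd import contaminate, crossing_angle_phantom

phantom = crossing_angle_phantom(70.0, shape=(12, 12, 12))
print(f"noiseless phantom: shape {phantom.signal.shape}, "
      f"{int((phantom.truth.count == 2).sum())} crossing voxels")

sos, prov_sos = contaminate(phantom.signal, snr=15.0, combiner="sos", seed=42)
smf, prov_smf = contaminate(phantom.signal, snr=15.0, combiner="smf", seed=42)
print(f"per-coil noise SD sigma = S0/SNR = {prov_sos['sigma']:.4f} "
      f"({prov_sos['n_coils']} coils, rho = {prov_sos['rho']})")

# the magnitude floor: background voxels contain pure noise, and the SoS
# combination carries the larger noncentral-chi bias
bg = phantom.truth.f_csf == 1.0
b0 = phantom.scheme.b0_mask
dwi_bg_sos = sos[bg][:, ~b0]
dwi_bg_smf = smf[bg][:, ~b0]
true_bg = phantom.signal[bg][:, ~b0].mean()
print(f"background true signal ~ {true_bg:.4f}")
print(f"measured background mean: SoS {dwi_bg_sos.mean():.4f}  "
      f"SMF {dwi_bg_smf.mean():.4f}")
print("the SoS floor sits higher: the 8-coil noncentral-chi bias "
      "(~3.94 sigma) versus the Rician floor (~1.25 sigma)")
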