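"""Reconstruct velocity and turbulent kinetic energy maps from the signals.

Velocity comes from the phase differences (u_i = phi_i * VENC / pi); the
intravoxel velocity standard deviation sigma_i comes from the magnitude
attenuation of each motion-encoded signal, and TKE = 1/2 rho sum sigma_i^2.
On a noise-free phantom both round-trip to floating precision.
"""

import numpy as np

from flowtke import (
    build_phantom,
    compute_velocity,
    default_spec,
    estimate_sigma,
    unwrap_velocity,
)

spec = default_spec(grid_shape=(48, 48, 48), n_frames=20, seed=0)
acq, seg, truth = build_phantom(spec)

vf = unwrap_velocity(compute_velocity(acq), acq.venc, truth.body_mask)
tm = estimate_sigma(acq)

vel_err = np.abs(vf.u - truth.true_velocity).max()
sig_err = np.abs(tm.sigma - truth.true_sigma).max()
print(f"max velocity error vs truth: {vel_err:.2e} m/s")
print(f"max sigma error vs truth   : {sig_err:.2e} m/s")
print(f"peak reconstructed TKE     : {tm.tke.max():.0f} J/m^3 "
      f"(truth {truth.true_tke.max():.0f})")
# Errors at the 1e-15 level show the estimator inverts the signal model
# exactly; with measurement noise they grow with 1/SNR instead.
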