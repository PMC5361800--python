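"""Undo the three phase-contrast artifacts and verify against truth.

Anti-aliasing recovers velocities beyond venc from neighborhood
consistency; the eddy-current fit recovers the injected first-order
offsets from static tissue to machine precision (noiseless case).
"""

import numpy as np

from aortaflow import PhantomSpec, simulate
from aortaflow.preprocess import (correct_eddy, detect_static_tissue,
                                  mask_noise, unwrap_velocity)

eddy = np.array([[0.05, 0.001, 0.0, 0.0],
                 [0.02, 0.0, 0.0005, 0.0],
                 [-0.01, 0.0, 0.0, 0.0002]])
spec = PhantomSpec(tube_radius=10.0, grid_shape=(36, 36, 28), voxel_size=2.0,
                   n_frames=8, v_profile="womersley", harmonics=(1.8, 0.25),
                   venc=(1.5, 1.5, 1.5), eddy_coeffs=eddy, seed=2)
data = simulate(spec)

noise = mask_noise(data.magnitude, 0.1)
print(f"noise-flagged voxels: {noise.sum()} (true air: {data.air_mask.sum()})")

unwrapped, n_fixed = unwrap_velocity(data.velocity)
print(f"unwrapped voxel-components: {n_fixed}")

static = detect_static_tissue(unwrapped, data.magnitude, sd_threshold=0.05)
corrected, fit = correct_eddy(unwrapped, static, order=1)
print(f"static voxels used for the eddy fit: {fit.n_static_voxels}")
print("recovered eddy coefficients (offset, d/dx, d/dy, d/dz):")
print(np.round(fit.coeffs, 6))
print("injected:")
print(eddy)
err = np.abs(corrected.values - data.truth_velocity).max()
print(f"max voxel error after full preprocessing: {err:.2e} m/s")
# Unwrapping is exact here; the residual comes from a few slow near-wall
# voxels that slip into the static-tissue mask and nudge the eddy fit.
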