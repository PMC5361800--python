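"""Wall shear stress on a steady parabolic-flow phantom vs the exact value.

For Poiseuille flow the wall shear stress is 2 mu v_max / R — here
2 * 3.2e-3 * 1.0 / 0.010 = 0.64 N/m^2, uniform over the wall.
"""

import numpy as np

from aortaflow import PhantomSpec, make_phantom
from aortaflow.anatomy import cap_vertices, extract_surface
from aortaflow.wss import compute_wss_frame

spec = PhantomSpec(tube_radius=10.0, grid_shape=(40, 40, 36), voxel_size=1.0,
                   n_frames=6, v_profile="poiseuille", v_max=1.0)
data = make_phantom(spec)

mesh = extract_surface(data.truth_mask)
caps = cap_vertices(mesh, data.truth_centerline)
wss, valid = compute_wss_frame(data.velocity, mesh, frame=0)
mags = np.linalg.norm(wss[valid & ~caps], axis=1)

print(f"wall vertices (caps excluded): {mags.size}")
print(f"mean |WSS|:  {mags.mean():.4f} N/m^2   (analytic 0.64)")
print(f"sd   |WSS|:  {mags.std():.4f} N/m^2")
print(f"relative error of the mean: {100 * (mags.mean() - 0.64) / 0.64:+.2f}%")
# At 20 voxels per diameter the wall-locating quadratic fit recovers the
# analytic shear to a few percent; the scatter reflects surface
# discretization, not flow structure.
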