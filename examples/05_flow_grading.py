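"""Grade helical flow by tracer winding: none / moderate / pronounced.

Phantoms with programmed transit rotations of 0, 180 and 450 degrees must
grade 0, 1 and 2 (thresholds 90 and 360 degrees of accumulated rotation
about the centerline).
"""

import numpy as np

from aortaflow import PhantomSpec, make_phantom
from aortaflow.flowpatterns import grade_region

for rotation in (0.0, 180.0, 450.0):
    v_axial = 0.5                      # m/s plug flow
    length_m = 31 * 2.0 * 1e-3         # tube length
    omega = np.radians(rotation) / (length_m / v_axial)
    spec = PhantomSpec(tube_radius=10.0, grid_shape=(36, 36, 32),
                       voxel_size=2.0, n_frames=8, v_profile="plug",
                       v_max=v_axial, swirl_rate=omega, seed=7)
    data = make_phantom(spec)
    g = grade_region(data.velocity, data.truth_mask, data.truth_centerline,
                     region="full", peak_frame=0, n_tracers=100, seed=7)
    print(f"programmed rotation {rotation:5.0f} deg -> "
          f"measured winding {g.max_winding:7.1f} deg, "
          f"helix grade {g.helix_grade}, vortex grade {g.vortex_grade}, "
          f"combined {g.combined}")
# The measured winding matches the programmed transit rotation because a
# tracer in solid-body swirl rotates at omega for exactly its transit time.
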