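"""Segment a U-bend 'aorta', partition its wall, report segmental WSS.

The U-bend stands in for the thoracic aorta: ascending limb, arch (the
bend) and descending limb. The wall is divided into five longitudinal
zones x inner/outer curvature = 10 segments.
"""

import numpy as np

from aortaflow import PhantomSpec, make_phantom
from aortaflow.anatomy import (cap_vertices, extract_centerline,
                               extract_surface, orient_centerline,
                               partition_segments)
from aortaflow.datatypes import SEGMENT_NAMES
from aortaflow.wss import compute_wss_map, segmental_mean_wss

spec = PhantomSpec(geometry="u_bend_tube", tube_radius=10.0, bend_radius=50.0,
                   leg_length=20.0, grid_shape=(64, 24, 48), voxel_size=2.5,
                   n_frames=6, v_profile="poiseuille", v_max=1.0)
data = make_phantom(spec)

mesh = extract_surface(data.truth_mask)
cl = extract_centerline(data.truth_mask)
cl = orient_centerline(cl, data.velocity, data.truth_mask, 0)
part = partition_segments(mesh, cl)
caps = cap_vertices(mesh, cl)

kmag = np.linalg.norm(cl.curvature, axis=1)
print(f"centerline length: {cl.length:.1f} mm "
      f"(analytic 2*20 + pi*50 = {2 * 20 + np.pi * 50:.1f})")
print(f"apex curvature: {kmag[len(kmag) // 2]:.4f} /mm (analytic 0.0200)")

wmap = compute_wss_map(data.velocity, mesh, peak=0, frames=[0])
report = segmental_mean_wss(wmap.wss_sys, part, mesh, wmap.valid & ~caps)
print("\nsegmental mean systolic WSS (N/m^2):")
for lab in range(1, 11):
    print(f"  {lab:2d} {SEGMENT_NAMES[lab]:<22s} {report.segment_wss[lab]:.3f}")
# With uniform parabolic inflow all ten segments sit near the analytic
# 0.64 N/m^2; on patient data the inner/outer contrast carries the signal.
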