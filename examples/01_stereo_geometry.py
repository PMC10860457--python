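"""Stereo localization with the dual-orthogonal kV geometry.

Projects a known 3D point onto both oblique imagers, back-projects the two
detector coordinates toward their sources, and intersects the rays to
recover the point. The residual is the closest-approach distance of the two
rays (zero for perfect detections).
"""

import numpy as np

from mdtt import (ImagingGeometry, RoomPoint, backproject_ray, intersect_rays,
                  project_point)

geom = ImagingGeometry(gantry_deg=30.0, ring_deg=-10.0)
p = RoomPoint(12.0, -35.0, 8.0)  # mm, (ML, SI, AP) from isocenter

pc_a = project_point(geom, p, "A")
pc_b = project_point(geom, p, "B")
print(f"imager A pixel: ({pc_a.u:.2f}, {pc_a.v:.2f})")
print(f"imager B pixel: ({pc_b.u:.2f}, {pc_b.v:.2f})")

hit = intersect_rays(backproject_ray(geom, pc_a), backproject_ray(geom, pc_b))
err = np.linalg.norm(hit.point.as_array() - p.as_array())
print(f"reconstructed: {np.round(hit.point.as_array(), 6)} mm")
print(f"residual {hit.residual:.2e} mm, error vs truth {err:.2e} mm")
# Both are at numerical precision: the stereo pair localizes any point near
# the isocenter exactly when the 2D detections are exact.
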