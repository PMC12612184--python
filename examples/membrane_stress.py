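"""Stress profile of the inflated chip membrane at the medium dome.

Finds the hydraulic pressure that inflates a 4 mm, 100 um, 530 kPa PDMS
membrane to the apex height of the 15-degree dome, then reports the
meridional and hoop stress summary over the centre (A1), slope (A2) and
edge (A3) regions.  The meridional-to-hoop ratio is 100 % at the apex
(axisymmetric isotropy) and grows toward the clamped rim — the spatial
stress gradient that cells on the chip experience.
"""

from curvchip.geometry import angle_to_geometry
from curvchip.mechanics import MembraneSpec, laplace_residual, region_partition, solve_for_apex_height

import numpy as np

h = angle_to_geometry(15.0, 4.0).apex_height_mm
spec = MembraneSpec(radius_mm=4.0, thickness_um=100.0, youngs_kpa=530.0,
                    target_apex_height_mm=h)
pressure, prof = solve_for_apex_height(spec)

print(f"target apex height : {h:.4f} mm (15-degree dome)")
print(f"matched pressure   : {pressure:.4f} kPa")
print(f"apex stress        : {prof.sigma_meridional_kpa[0]:.2f} kPa (isotropic)")
res = np.max(np.abs(laplace_residual(prof))) / (pressure / spec.thickness_mm)
print(f"equilibrium residual: {res:.2e} of p/t")
print()
print(f"{'region':>7} {'sigma_m (kPa)':>14} {'sigma_h (kPa)':>14} {'m/h ratio (%)':>14}")
for name, reg in region_partition(prof).items():
    print(
        f"{name:>7} {reg.mean_meridional_kpa:>14.2f} "
        f"{reg.mean_hoop_kpa:>14.2f} {reg.ratio_percent:>14.1f}"
    )
# Hoop stress dominates the centre; meridional stress overtakes it at the
# edge, so the ratio climbs from ~100 % (A1) toward ~150 % (A3).
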