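"""Convert measured dome chord angles to full spherical-cap descriptors.

The three chip curvature levels are defined by the chord angle measured
in side-view images; everything else — radius of curvature, keratometric
power, apex height, cap volume — follows from spherical-cap geometry.
"""

from curvchip.geometry import angle_to_geometry, radius_to_diopters

print(f"{'phi (deg)':>10} {'R (mm)':>8} {'D (diopters)':>13} {'h (mm)':>8} {'V (uL)':>8}")
for label, phi in (("flat", 0.0), ("low", 11.79), ("medium", 15.0), ("high", 20.91)):
    g = angle_to_geometry(phi, well_radius_mm=4.0)
    r = "inf" if g.radius_mm == float("inf") else f"{g.radius_mm:.3f}"
    print(
        f"{g.chord_angle_deg:>10.2f} {r:>8} {g.power_display:>13.2f} "
        f"{g.apex_height_mm:>8.3f} {g.cap_volume_ul:>8.2f}   ({label})"
    )

print()
print(f"Healthy cornea, R = 7.8 mm: {radius_to_diopters(7.8):.2f} D (~43 D)")
# The low/medium/high rows bracket the clinically relevant 33-56 D range:
# cornea plana sits below 36 D, keratoconus/keratoglobus above 45 D.
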