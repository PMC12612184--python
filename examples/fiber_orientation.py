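"""Structure-tensor alignment analysis of an orthogonal fibre layer.

Renders two fibre families 90 degrees apart (the lamellar organisation
fibroblasts adopt on curved substrates), builds the normalised angular
histogram, and reports the crossing angle theta_cross plus the fraction
of orientation weight within +/-10 degrees of each family axis.
"""

from curvchip.orientation import (
    alignment_efficiency,
    build_histogram,
    orientation_field,
    theta_cross,
)
from curvchip.synthdata import ImageRecipe, make_image

recipe = ImageRecipe(
    size_px=512,
    n_nuclei=0,
    n_fibers=150,
    orientation_model="two-family",
    orientation_mu_deg=0.0,
    orientation_kappa=100.0,
    mixture_angle_deg=90.0,
    fiber_channel_amps={"green": 100.0},
    seed=4,
)
channels, truth = make_image(recipe)

field = orientation_field(channels["green"])
hist = build_histogram(field)
raw, acute = theta_cross(hist)
peaks = hist.peaks()[:2]

print(f"programmed family axes : 0 and 90 deg (kappa = 100)")
print(f"histogram modes        : {peaks[0][0]:+.1f} and {peaks[1][0]:+.1f} deg")
print(f"theta_cross            : raw {raw:.2f} deg, acute {acute:.2f} deg")
for axis in (0.0, 90.0):
    eff = alignment_efficiency(hist, axis, half_window_deg=10.0)
    print(f"efficiency within +/-10 deg of {axis:>4.0f} deg axis: {eff:.3f}")
# theta_cross near 90 deg confirms orthogonal lamellar organisation; each
# family holds roughly half the orientation weight inside its window.
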