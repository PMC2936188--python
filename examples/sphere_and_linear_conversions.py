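"""Sphere volume/diameter and linear↔volumetric response conversions.

Run:  python examples/sphere_and_linear_conversions.py
"""

from volprec import (
    equivalent_sphere_diameter,
    linear_change_to_volume,
    pixel_error_linear_fraction,
    pixel_size,
    sphere_volume,
    volume_change_to_linear,
)

for d in (10.0, 20.0, 30.0):
    print(f"sphere d = {d:.0f} mm  ->  V = {sphere_volume(d):.2f} cm3")
print(f"V = 4.5 cm3  ->  equivalent sphere d = {equivalent_sphere_diameter(4.5):.1f} mm")
print()

# a 30% linear shrinkage (the classic unidimensional partial-response cut)
remaining = 1.0 + linear_change_to_volume(-0.30)
print(f"-30% linear  ->  remaining volume fraction {remaining:.3f}")

# volume growth thresholds expressed as linear growth
for dv in (0.130, 0.178):
    print(f"+{100*dv:.1f}% volume  ->  +{100*volume_change_to_linear(dv):.1f}% linear")
print()

# the pixel-positioning argument: one pixel on a small lesion is already
# larger than the linear change of a statistically detectable volume change
px = pixel_size(350.0, 512)
err = pixel_error_linear_fraction(px, 12.8, n_pixels=1)
print(f"pixel = 350/512 = {px:.2f} mm; 1-pixel error on a 12.8 mm lesion = "
      f"{100*err:.1f}% linear")
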