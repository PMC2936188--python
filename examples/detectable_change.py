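"""Minimal statistically detectable volume change for a test-retest series.

Run:  python examples/detectable_change.py
"""

from volprec import (
    classify_change,
    expected_aging_drift,
    min_detectable_volume_change,
    significance_of_observed_change,
)

# 20 repeated measurements of a stable ~3.4 cm³ organ, sample SD 0.64 cm³
mean, sd, n = 3.4, 0.64, 20

for alpha in (0.05, 0.01):
    r = min_detectable_volume_change(mean, sd, n, alpha=alpha)
    print(
        f"alpha = {alpha:4}: detectable volume change "
        f"{100*r.min_detectable_volume_fraction:5.2f}% "
        f"(linear {100*r.equivalent_linear_fraction:.2f}%)"
    )

p = significance_of_observed_change(mean, sd, n, observed_fraction=0.20)
print(f"an observed +20% change has p = {p:.4f}")

# the ~18% precision threshold for adrenal-sized objects
for obs in (0.10, 0.25):
    print(f"observed {100*obs:.0f}% vs 18% COV -> {classify_change(obs, 0.18)}")

# slow physiologic drift is negligible next to measurement noise
print(f"aging drift of a 5.2 cm3 gland over 5.25 yr: "
      f"{100*expected_aging_drift(5.2, 5.25):.1f}%")
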