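"""Fluorometric enzyme quantification: fit a 4-MU standard curve (10 uM,
2-fold dilutions) and convert sample fluorescence to specific activity."""

import numpy as np

import hdxkit as h

conc_um = 10.0 / 2 ** np.arange(8)          # 10, 5, 2.5 ... uM
fluorescence = 1000.0 * conc_um + 20.0       # plate-reader response
curve = h.fit_standard_curve(conc_um, fluorescence)
print(
    f"standard curve: slope {curve.slope:.1f} AU/uM, "
    f"intercept {curve.intercept:.1f} AU, r^2 {curve.r_squared:.4f}"
)

activity = h.gus_activity(2520.0, curve, protein_mg=0.05, minutes=30.0)
print(f"sample activity: {activity:.4f} uM 4-MU per mg protein per min")
print()
print(
    "Fluorescence converts to product concentration via the line, then "
    "normalizes\nby protein amount and incubation time."
)
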