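"""Ground-truth round trip: generate, perturb, reconcile, localize.

Creates an exactly balanced truth for the late-exponential stage, corrupts
the ethanol measurement with a 5-sigma bias on top of 5% noise, and shows the
consistency test catching it and serial elimination pointing at the culprit.
"""

import numpy as np

from oenoflux.reconcile import MeasurementSet, localize_gross_error, reconcile
from oenoflux.simulate import generate_toy_truth

names, E, r_true = generate_toy_truth("II")
print("balanced truth (mmol/gDCW/h):")
print("  " + "  ".join(f"{n}={v:.2f}" for n, v in zip(names, r_true)))

rng = np.random.default_rng(3)
sd = np.maximum(0.05 * np.abs(r_true), 1e-3)

clean = MeasurementSet(names=names, r_m=r_true + rng.normal(0, sd), sd=sd.copy())
res = reconcile(clean, E)
print(f"\nclean replicate:  h = {res.h:.2f} < {res.critical_value:.2f} -> {res.verdict}")

biased = clean.r_m.copy()
i = names.index("ethanol")
biased[i] += 5 * sd[i]
ms = MeasurementSet(names=names, r_m=biased, sd=sd.copy())
res = reconcile(ms, E)
print(f"ethanol +5 sigma: h = {res.h:.2f} >= {res.critical_value:.2f} -> {res.verdict}")

print("\nserial elimination (h after removing each measurement, ascending):")
for name, h in localize_gross_error(ms, E):
    marker = "  <- suspected gross error" if name == "ethanol" else ""
    print(f"  {name:>10s}: h = {h:6.2f}{marker}")

print(
    "\nRemoving the corrupted ethanol rate collapses the consistency index;"
    "\nremoving any honest measurement leaves the violation in place."
)
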