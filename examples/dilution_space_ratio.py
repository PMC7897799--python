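"""The body-mass dependence of the dilution-space ratio.

Evaluates the asymptotic-exponential DSR curve at a few masses, then
refits its constants from noise-free samples of the curve to show the
constrained fitter recovers them exactly.
"""

import numpy as np

from dlwcalc import dsr_from_mass, fit_dsr_model

print("DSR(BM) = 1.036 - 0.05 * exp(-0.5249 * BM)")
for mass in (0.5, 1.0, 2.0, 4.0, 10.0, 20.0, 70.0):
    print(f"  BM = {mass:5.1f} kg  ->  DSR = {dsr_from_mass(mass):.4f}")

masses = np.arange(0.5, 10.01, 0.5)
fit = fit_dsr_model(masses, [dsr_from_mass(m) for m in masses],
                    fixed_asymptote=1.036)
print(f"\nconstrained refit from {len(masses)} noise-free points:")
print(f"  amplitude = {fit.params.amplitude:.6f} (true 0.05)")
print(f"  rate      = {fit.params.rate:.6f} kg^-1 (true 0.5249)")
print()
print("Small babies have proportionally smaller 2H dilution spaces; the")
print("curve rises from ~1.019 in preterm infants toward the adult 1.036,")
print("letting one continuous equation replace per-size-class variants.")
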