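"""Compute CO2 production and energy expenditure for one adult subject.

Builds a single isotope-kinetics record (elimination rates, dilution
spaces, body mass, respiratory quotient), runs the automatic equation
selection and converts the resulting rCO2 to total energy expenditure.
"""

from dlwcalc import IsotopeKinetics, compute_rco2, weir_tee

subject = IsotopeKinetics(
    subject_id="demo-adult",
    ko=0.12,       # 18O elimination rate, d^-1
    kd=0.10,       # 2H elimination rate, d^-1
    No=2014.0,     # 18O dilution space, mol
    Nd=2086.0,     # 2H dilution space, mol
    body_mass=80.0,
    rq=0.85,
)

result = compute_rco2(subject)           # auto: adult equation at >= 10 kg
energy = weir_tee(result.rco2, subject.rq)

print(f"equation used : {result.equation_id} (DSR {result.dsr_used})")
print(f"body water    : {result.pool_size_used:.1f} mol "
      f"({result.pool_convention})")
print(f"rCO2          : {result.rco2:.1f} L/d")
print(f"TEE           : {energy.tee_mj_per_day:.2f} MJ/d "
      f"({energy.tee_kcal_per_day:.0f} kcal/d)")
print()
print("rCO2 is the CO2 production implied by the difference between the")
print("18O and 2H elimination fluxes from body water; TEE converts it to")
print("energy via the Weir equation at the subject's RQ.")
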