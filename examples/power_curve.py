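"""Chemical power curve of flapping flight for a 130-g falcon.

Builds the Pennycuick-style curve (induced + parasite + profile power,
converted to chemical power through muscle efficiency and respiration
overhead, plus the measured resting rate as maintenance), and prints the
two characteristic speeds: Vmp, where flight is cheapest per unit time,
and Vmr, where it is cheapest per unit distance.
"""

from soartrack import power_curve, resting_power

p_rest = resting_power(4.03, 20.1)   # measured by respirometry
curve = power_curve(maintenance_power_w=p_rest)

print(f"resting metabolic rate     : {p_rest:.2f} W")
print(f"minimum power speed  (Vmp) : {curve.vmp_kmh:.2f} km/h")
print(f"maximum range speed  (Vmr) : {curve.vmr_kmh:.2f} km/h")
print(f"chemical power at Vmp      : {curve.p_chem_at_vmp_w:.2f} W")
print(f"chemical power at Vmr      : {curve.p_chem_at_vmr_w:.2f} W")
print()
print("Flying at Vmr is faster but costs more per second; the ratio of the")
print("two powers tells how much a bird pays for speed on a commute.")
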