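"""Derive adult-anchored nutritional-status cutoffs.

Fixes the adult values 17 / 25 / 30 kg/m^2 (underweight / overweight /
obesity) at late-adolescent anchor ages and traces the centile each value
occupies back through childhood.
"""

from abmiref import derive_standard_cutoffs, load_packaged_reference

ref = load_packaged_reference()
cuts = derive_standard_cutoffs(ref)

print(f"{len(cuts)} cutoff sets (anchor value x anchor age x sex)\n")
print("label        sex anchor(mo) z*      percentile  value@120mo")
for c in cuts:
    if c.anchor_age_months != 216:
        continue
    at120 = c.curve.values[c.curve.ages == 120][0]
    print(
        f"{c.label:<12s} {c.sex}   {c.anchor_age_months:.0f}       "
        f"{c.z_star:+.3f}  {c.percentile:6.2f}      {at120:.2f}"
    )
print(
    "\nEach curve passes through its anchor value at the anchor age; the\n"
    "value@120mo column is the equivalent ABMI threshold at age 10 y."
)
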