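"""Enumerate the six W/Z/Y parental combinations and their expectations.

Females can be WW or WZ and males ZZ, ZY or WY, so parents combine in six
ways.  Each cross implies an offspring genotype distribution, an expected
sex ratio, and whether paternal (Y) or maternal (W) variation is completely
sex-linked.
"""

from trisexscan.model import (
    cross_expectation,
    enumerate_crosses,
    null_full_linkage_probability,
)

for cross in enumerate_crosses():
    exp = cross_expectation(cross)
    dist = ", ".join(f"{g}:{p}" for g, p in sorted(exp.offspring_dist.items(), key=lambda kv: str(kv[0])))
    print(
        f"{cross}: offspring {{{dist}}}  female fraction {exp.female_fraction}"
        f"  paternal-Y-linked {exp.complete_paternal_Y_linkage}"
        f"  maternal-W-linked {exp.complete_maternal_W_linkage}"
    )

print()
print("Only WZ x ZY skews the sex ratio (1 female : 3 males); the three")
print("crosses with complete paternal Y linkage are where every son and no")
print("daughter inherits the father's Y.")

p = null_full_linkage_probability(15, 14)
print()
print(f"P(15/15 males het and 0/14 females het | no sex linkage) = {p:.3g}")
print("A marker this concordant with sex is overwhelming evidence of Y linkage.")
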