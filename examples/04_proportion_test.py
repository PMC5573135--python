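"""Compare the share of within-representation participants across conditions.

The pooled two-proportion z test asks whether training methodology shifts
how many participants end up best fit by the density (within-category)
model. With rule-based categories, concept (Yes/No) training yields 21/31
density-fit participants against 12/30 under classification (A/B) training;
with information-integration categories the split is 24/30 vs 21/29.
"""

from catrep import two_proportion_z

z_rb = two_proportion_z(21, 31, 12, 30)
z_ii = two_proportion_z(24, 30, 21, 29)

print(f"rule-based structures:              z = {z_rb:.2f}  (21/31 vs 12/30)")
print(f"information-integration structures: z = {z_ii:.2f}  (24/30 vs 21/29)")

# |z| > 1.96 is significant at the 5% level: training methodology shifts the
# representation mix for rule-based categories (z = 2.17) but not for
# information-integration categories (z = 0.68).
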