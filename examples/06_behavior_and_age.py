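"""Behavioral severity scoring and the mouse-to-human age conversion."""

from purinomics import age_equivalent, pbrs_total
from purinomics.physiology import PBRS_ITEMS

# A strongly affected animal 15 minutes post-injection: every feature
# present, four of them severe.
scores = [2, 2, 2, 2, 1, 1]
for item, s in zip(PBRS_ITEMS, scores):
    print(f"  {item}: {s}")
print(f"PBRS total: {pbrs_total(scores)} (scale 0-12)")

for months in (1, 2, 6, 8, 12):
    print(f"{months}-month-old mouse ~ {age_equivalent(months):.1f} human years")
# The conversion is piecewise: development is fastest early in life
# (12 years for the first month) and settles to 2.5 years per month.
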