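"""Cortical surface-area reduction after neonatal enucleation.

Uses the published cat group means (three control, three enucleated-at-birth
subjects): striate cortex 339.46 -> 204.36 mm^2 and extrastriate cortex
510.75 -> 332.70 mm^2.
"""

from cortexclock import AreaMeasure, percent_reduction, summarize_groups
from cortexclock.areas import format_reduction

print("direct arithmetic on the group means:")
print("  striate:     ", format_reduction(percent_reduction(339.46, 204.36)))
print("  extrastriate:", format_reduction(percent_reduction(510.75, 332.70)))

# the same numbers via per-subject measures (synthetic subjects whose means
# equal the published group means)
measures = []
for region, ctrl, trt in [("striate", 339.46, 204.36), ("extrastriate", 510.75, 332.70)]:
    for i, d in enumerate((-12.0, 0.0, 12.0)):
        measures.append(AreaMeasure(region, "control", ctrl + d, f"c{i}"))
        measures.append(AreaMeasure(region, "treated", trt + d, f"t{i}"))

summary = summarize_groups(measures)
print("per-subject route (three subjects per group):")
for region, pct in summary.reductions.items():
    print(f"  {region}: {format_reduction(pct)}")
print("a ~40% striate loss with no respecification of neighbouring cortex is")
print("the adult signature of enucleation before birth in the cat")
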