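"""Translate the rat critical period onto the human and ferret FA clocks.

The rat critical period for callosal-connection specification is postnatal
days 4-6 (25.5-27.5 days post conception).  Expressed as the fraction of the
cortical-FA range still remaining, those bounds are exp(-0.7) ~ 0.50 and
exp(-1.1) ~ 0.33; matching the same fractions on another species' clock
predicts when the equivalent developmental stage occurs there.
"""

from cortexclock import (
    DevWindow,
    compare_to_translating_time,
    decay_fraction,
    default_registry,
    pn_to_pc,
    translate_window,
    TT_HUMAN_FROM_RAT,
)
from cortexclock.rounding import round_half_away

registry = default_registry()
rat = registry["rat"].require_fa()

start = pn_to_pc(4.0, rat.gestation_days)
end = pn_to_pc(6.0, rat.gestation_days)
window = DevWindow("rat", start, end)
print(f"rat critical period: P4-P6 = PC{start}-PC{end}")
print(
    "decay fractions at the bounds: "
    f"{decay_fraction(rat, start):.2f} and {decay_fraction(rat, end):.2f}"
)

for target in ("human", "ferret"):
    params = registry[target].require_fa()
    w = translate_window(window, rat, params)
    print(
        f"{target}: PC {w.start_pc:.1f}-{w.end_pc:.1f} days "
        f"-> reported PC{round_half_away(w.start_pc):.0f}-"
        f"PC{round_half_away(w.end_pc):.0f}"
    )

# how far the FA-based human prediction sits from the Translating Time one
human_w = translate_window(window, rat, registry["human"].require_fa())
cmp = compare_to_translating_time(human_w, TT_HUMAN_FROM_RAT)
print(
    "FA-based human window is "
    f"{cmp['start_offset_days']:.0f}/{cmp['end_offset_days']:.0f} days later "
    "than the Translating Time window (138-150 gestational days); "
    f"overlap: {cmp['windows_overlap']}"
)
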