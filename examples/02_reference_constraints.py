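"""Apply the reference-strain (CS5-style) constraint preset and solve.

The preset encodes the measured physiology: glucose uptake <= 20
mmol/gDW/hr, biomass fixed at 1.706, chrysanthemol secretion floored at
0.0023, the MVA:MEP route ratio pinned at 6461:1 and a Δ=0.4 cap on DMAPP
branch consumption relative to precursor-route supply.
"""

from debranch import baseline_flux, cs5_preset, make_toy_model
from debranch.synth import TOY_CS5_ALIASES

model, _ = make_toy_model()
preset = cs5_preset(model, aliases=TOY_CS5_ALIASES)
state = baseline_flux(model, preset, objective="BIOMASS_toy")

print(f"biomass flux        : {state['BIOMASS_toy']:.4f} mmol/gDW/hr (fixed)")
print(f"chrysanthemol flux  : {state['EX_CS_OH']:.4f} mmol/gDW/hr (floor)")
print(f"glucose uptake      : {-state['EX_glc__D_e']:.4f} mmol/gDW/hr (cap 20)")
print(f"MVA:MEP route ratio : {state['DPMVD'] / state['CDPMEK']:.1f} (pinned 6461)")
cap = preset.group_caps[0]
consumed = sum(max(state[r], 0.0) for r in cap.consumers)
produced = sum(max(state[r], 0.0) for r in cap.producers)
print(f"DMAPP cap usage     : {consumed:.4f} <= {cap.delta} x {produced:.4f}")
# The parsimonious baseline sits exactly on the measured operating point;
# the cap still has slack, so debranching has room to act.
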