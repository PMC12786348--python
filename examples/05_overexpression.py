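"""Sweep the dehydrogenase capacities to find the conversion bottleneck.

Base capacities come from kinetics x expression (ADH2 step 2.0, ALDH1 step
0.5 mmol/gDW/hr, so RVmax = 4); the sweep scales each bound n-fold.
"""

from debranch import cs5_preset, make_toy_model, sweep_overexpression
from debranch.synth import TOY_CS5_ALIASES, ToySpec

spec = ToySpec()
model, truth = make_toy_model(spec)
preset = cs5_preset(model, aliases=TOY_CS5_ALIASES)
preset.bounds["ADH2"] = (-spec.adh_vmax, spec.adh_vmax)
preset.bounds["ALDH1"] = (-spec.aldh_vmax, spec.aldh_vmax)

surface = sweep_overexpression(
    model, preset, "ADH2", "ALDH1", product_rxn="EX_CS_acid",
)
print("n      f1-only  f2-only  joint   (chrysanthemic acid, mmol/gDW/hr)")
f1, f2, joint = surface.f1_only(), surface.f2_only(), surface.joint()
for i, n in enumerate(surface.n_grid):
    print(f"{n:<6.0f} {f1.product_flux[i]:7.3f}  {f2.product_flux[i]:7.3f}  "
          f"{joint.product_flux[i]:6.3f}")
# Scaling the alcohol step alone does nothing (flat column): the aldehyde
# step is the bottleneck. Scaling it alone helps until the alcohol step
# binds; co-amplifying both unlocks the upstream supply ceiling.
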