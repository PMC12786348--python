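"""Simulate graded silencing of the dominant branch (the ispA analogue).

Bounds on the prenyltransferase pair are divided by 2..256 starting from
their baseline fluxes; each level is re-solved with biomass maximized
first and chrysanthemol secretion second.
"""

from debranch import cs5_preset, make_toy_model, simulate_knockdown, yield_improvement
from debranch.synth import TOY_CS5_ALIASES

model, truth = make_toy_model()
preset = cs5_preset(model, aliases=TOY_CS5_ALIASES)

curve = simulate_knockdown(
    model, preset, targets=["DMATT", "GRTT"],
    product_rxn="EX_CS_OH", biomass_rxn="BIOMASS_toy",
)
cols = ["factor", "flux_product", "flux_biomass", "fold_change"]
print(curve.frame[cols].to_string(index=False,
                                  float_format=lambda v: f"{v:.4f}"))
ratios = yield_improvement(curve)
print(f"\nbest improvement: {ratios.attrs['max_ratio']:.1f}-fold at "
      f"{ratios.attrs['argmax_factor']:.0f}-fold inhibition")
# Product secretion rises monotonically as the branch is throttled, while
# biomass falls — knockdown trades growth for product without the lethality
# of a full knockout.
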