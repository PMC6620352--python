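"""Above-ground carbon totals and their breakdown by dispersal mode.

Per-stem biomass comes from the moist-forest allometry
AGB = rho * exp(-1.499 + 2.148 lnD + 0.207 (lnD)^2 - 0.0281 (lnD)^3) [kg],
carbon is AGB/2, and every stem is assigned to one exclusive category:
P (primate-dispersed), TB (large terrestrial mammals / large birds), or
O (all other agents).
"""

from defaunasim import SynthConfig, generate
from defaunasim.biomass import agc_shares, total_agc

census, traits = generate(SynthConfig(seed=1))

total_mg, per_ha = total_agc(census, traits, plot_area_ha=30.0)
print(f"plot AGC: {total_mg:,.1f} Mg over 30 ha  ({per_ha:.1f} Mg/ha)")
print(agc_shares(census, traits).round(1).to_string(index=False))
# P + TB is the carbon held by trees that depend on large-bodied
# frugivores for dispersal — the fraction at stake under defaunation.
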