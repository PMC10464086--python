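"""Sediment gas volume, total interstitial space, and age-depth dating.

Builds the dated anchor set of a dammed-lake core (surface 2015, the
damming horizon at 21.4 cm in 1963, core bottom 55 cm at ~306 yr) and a
small physics table, then computes deposition rates and gas fractions.
"""

import pandas as pd

from sedstrat import AgeDepthModel, gas_volume_percent, interstitial_table

model = AgeDepthModel([(0, 2015), (21.4, 1963), (55, 2015 - 306)])
upper = model.deposition_rate(0, 21.4)
lower = model.deposition_rate(21.4, 55)
print(f"deposition rate above the damming horizon: {upper:.2f} cm/yr")
print(f"deposition rate below the damming horizon: {lower:.2f} cm/yr")
print(f"post/pre-damming ratio: {upper / lower:.1f}x")
print(f"sediment at 30 cm dates to ~{model.depth_to_year(30):.0f} AD")

# a saturated layer (no gas) and a methane-charged layer
physics = pd.DataFrame(
    {
        "layer": [1, 8],
        "moi_v": [0.80, 0.60],
        "moi_m": [0.60, 0.50],
        "rho_w": [1.00, 1.00],
        "rho_ws": [1.333, 1.50],
    }
)
table = interstitial_table(physics)
print(table[["layer", "vp_a", "tis", "warning"]].to_string(index=False))
print("worked example VP_a(0.6, 0.5, 1.0, 1.5) =",
      round(gas_volume_percent(0.6, 0.5, 1.0, 1.5), 3))
# The gas fraction VP_a is the free-methane share of the layer volume; TIS
# (water + gas) is the total interstitial space a microbe experiences.
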