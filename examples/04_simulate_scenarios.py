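"""Run the growth-and-harvest simulator under business-as-usual and an
intensification scenario mobilizing harvest-delayed stands.

The simulator advances every plot in 5-yr steps (growth, mortality,
thinning, clearcut at the diameter threshold).  Under scenario D-10,
all harvest-delayed area is progressively mobilized over 30 years,
largest diameters first; the extra harvest is transient, drawing down
the legacy biomass stock.
"""

from sylvasim import scenarios, synthetic
from sylvasim.growth import (GrowthParams, SpeciesGrowth,
                             build_regrowth_library, run_simulation)
from sylvasim.inventory_io import default_species_table
from sylvasim.management import classify

plots, trees, truth = synthetic.legacy_stock_inventory(
    synthetic.legacy_config(seed=5, n_plots=1000))
classified = classify(plots, truth.thresholds)
gp = GrowthParams({n: SpeciesGrowth(n, {"": s.a_intercept}, s.a_di, s.a_age, 0.0,
                                    {"": s.b_intercept}, s.b_di, s.b_age, 0.0)
                   for n, s in truth.species.items()})
mr = {n: s.mortality for n, s in truth.species.items()}
lib = build_regrowth_library(classified)
table = default_species_table()

for label, spec in [("BaU", scenarios.build_scenario("BaU")),
                    ("D-10", scenarios.build_scenario("D", 10))]:
    traj = run_simulation(classified, gp, mr, truth.thresholds, lib, spec,
                          horizon=50, species_table=table)
    yearly = traj.harvest.groupby("year")["volume_m3"].sum() / 1e6
    total = traj.harvest["volume_m3"].sum() / 1e6
    print(f"{label}: {total:.2f} Mm³ harvested over 50 yr; per 5-yr step:",
          ", ".join(f"{y:.0f}:{v:.2f}" for y, v in yearly.items()))

print("(the D-10 surplus peaks mid-ramp and fades once the accumulated "
      "stock of over-mature stands is consumed)")
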