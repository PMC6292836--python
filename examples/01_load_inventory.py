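"""Generate a small synthetic inventory, round-trip it through CSV, and
upscale plot volumes to national totals with the shipped species table.

The species table carries the national per-species areas; upscaling
multiplies the equal-weight mean standing volume of each species × region
cell by the cell's area share.
"""

import tempfile
from pathlib import Path

from sylvasim import inventory_io as io, synthetic

plots, trees, truth = synthetic.generate_inventory(
    synthetic.GeneratorConfig(seed=42, n_plots=200))

with tempfile.TemporaryDirectory() as d:
    io.write_plot_table(plots, Path(d) / "plots.csv")
    io.write_tree_table(trees, Path(d) / "trees.csv")
    plots = io.read_plot_table(Path(d) / "plots.csv")
    trees = io.read_tree_table(Path(d) / "trees.csv")

table = io.default_species_table()
print(f"national forest area: {table.total_area_km2():,.0f} km², "
      f"standing volume {table.total_volume_Mm3():,.0f} Mm³")

national = io.upscale(plots, table)
v = national.loc["Fagus sylvatica", "V_total_m3"] / 1e6
print(f"{len(plots)} plots, {sum(len(t) for t in trees.values())} tree records")
print(f"upscaled beech standing volume: {v:.1f} Mm³ "
      "(plot-mean m³/ha × reported species area)")
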