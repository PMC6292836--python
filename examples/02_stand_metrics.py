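"""Derive the per-stand indices the simulator is built on.

Fits the Hossfeld guide curve (dominant height vs age) and the
self-thinning frontier (max stem number vs mean diameter) to a synthetic
inventory, then shows the site index and relative density index of one
plot, and the stand increments reconstructed from its tree records.
"""

from sylvasim import stand_metrics as sm, synthetic

plots, trees, truth = synthetic.generate_inventory(
    synthetic.noise_free_config(seed=7, n_plots=400))

guide = sm.fit_guide_curve([p.age for p in plots], [p.h0 for p in plots])
print(f"guide curve: a={guide.a:.2f} m, b={guide.b:.1f} yr, c={guide.c:.3f} "
      f"-> H100 = {guide.H100:.1f} m (height a typical stand reaches at 100 yr)")

frontier = sm.fit_self_thinning([p.Dg for p in plots], [p.N for p in plots],
                                [p.age for p in plots])
print(f"self-thinning frontier: log N_max = {frontier.g:.2f} "
      f"{frontier.h:+.2f} log Dg (maximum stocking at a given diameter)")

p = plots[0]
h100 = sm.site_index(p.h0, p.age, guide)
di = sm.density_index(p.N, p.Dg, frontier)
print(f"plot {p.plot_id}: age {p.age:.0f} yr, h0 {p.h0:.1f} m -> "
      f"site index {h100:.1f} m; N={p.N:.0f}/ha at Dg={p.Dg:.1f} cm -> DI={di:.2f} "
      "(1 = at the self-thinning limit)")

vr = sm.fit_volume_radius([t for recs in trees.values() for t in recs])
sp = truth.species[p.main_species]
iv, ir, _ = sm.stand_increments(trees[p.plot_id], p.main_species,
                                {p.main_species: vr}, {p.main_species: sp.beta})
print(f"reconstructed 5-yr increments: volume {iv:.2f} m³/ha, "
      f"radius {ir * 1000:.2f} mm (inputs of the growth model fit)")
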