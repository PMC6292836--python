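# sylvasim

An inventory-calibrated forest growth-and-harvest simulator with
wood-use-chain carbon accounting, built around the question national
forest agencies and carbon analysts keep returning to: *if a country
intensifies forest management to meet a bioenergy target, what happens
to the carbon balance of its forestry sector, and when — if ever — does
the extra harvest pay back its carbon debt?*

The package implements the full pipeline for the French case: plot-level
inventory tables are turned into stand descriptors, every stand is
classified into one of four management approaches, an empirical
simulator projects growth and harvest under business-as-usual and
intensification scenarios, and the harvested wood is followed through
the national wood-use chain into product pools, energy, and avoided
fossil emissions.  Because the underlying national inventory microdata
(plot coordinates and statistical weights) are not public, the package
ships a synthetic-inventory generator that reproduces the statistical
structure the pipeline assumes, with known ground truth — every
estimator and every accounting identity is testable without any
download.

## The model

**Stand description.** Dominant height follows a Hossfeld II guide curve
per species, `h0(age) = a / (1 + (b/age)^c)`; the site index H100 of a
plot transfers proportionally along it, `H100 = h0 · h0_guide(100) /
h0_guide(age)`.  Stocking is measured by the relative density index
`DI = N / N_max(Dg)` against a self-thinning frontier
`log N_max = g + h·log Dg` fitted as the upper envelope of the log-log
cloud.  Stand-level 5-yr increments are reconstructed from tree records:
`iv = v·(1 − f(r_{t−5})/f(r_t))` with a power-law stem allometry
`f(r) = k·r^m` and `r_{t−5} = ((1−β)r − ir)/(1−β)` from the below-bark
radius increment and bark ratio β.

**Growth and harvest.** Two independent log-linear models drive the
5-yr step:

```
log IV = a_H100 + a_DI·log DI + a_age·log age + ε
log Ir = b_H100 + b_DI·log DI + b_age·log age + ε
```

plus species mortality as a yearly fraction of standing volume.
Actively-managed stands are thinned (yearly ratio, compounded within the
step) and clearcut once the quadratic mean diameter
`Dg = 100·√(4G/πN)` reaches the species × fertility threshold; the plot
is then replaced by a young regrowth stand.  Thresholds are detected as
discontinuities in the empirical diameter and density distributions
(two-segment histogram fit, SSE scan) and can be calibrated against
reported harvest.  Scenario families intensify management by thinning
overstocked stands (O_v), harvesting harvest-delayed stands (D), or
lowering clearcut diameters (M), each with a 30-yr linear mobilization
ramp; A combines all three.

**Carbon accounting.** Harvest enters the timber / pulp & industry /
energy pathways (hardwood 16/14/70 %, softwood 53/23/24 %, or by
source), is processed (sawing residues cascade to pulp and energy), and
fills product pools that decay exponentially (timber 50 yr, paper 40 yr,
energy 1.7 yr).  Extra products relative to the reference earn
substitution credits (timber 1.2, pulp 0.53, energy 0.5 tC avoided per
tC).  The ledger sums the in-situ stock, the product stock, and the
cumulative substitution credit; the carbon efficiency of bioenergy is
the cumulative balance per cumulative Mtoe, and the parity time is the
year an intensification scenario's balance catches back up with the
reference.

## Worked example

`examples/05_wood_chain_carbon.py` classifies a 1000-plot synthetic
legacy-stock inventory, runs business-as-usual and two intensification
scenarios for a century, and prints:

```
100 m³ of hardwood harvest -> 16 timber / 14 pulp & industry / 70 energy m³
BaU carbon efficiency by 2115: 1.32 Mt C per Mtoe (cumulative balance over
cumulative energy; declines as stands mature)
M-10: balance vs BaU at 2045 +0.09 Tg C; carbon parity in 2115
D-10: balance vs BaU at 2045 +0.01 Tg C; carbon parity never within the horizon
```

The first line is the national hardwood allocation applied to a toy
harvest.  The efficiency line says each Mtoe of bioenergy under
continued present-day management coincides with 1.32 Mt of carbon
sequestered over the century — a number that falls as the simulated
forest matures.  The scenario lines compare each intensification against
the reference: on this fixture, shortening rotations (M-10) recovers its
carbon debt by the end of the horizon while mobilizing harvest-delayed
stands (D-10) does not.  The other examples walk the earlier pipeline
stages (I/O and upscaling, stand metrics, classification, simulation).

## Layout

| module | role |
| --- | --- |
| `sylvasim.inventory_io` | table data model, CSV readers/writers, upscaling |
| `sylvasim.stand_metrics` | guide curve, site index, frontier, DI, allometry, increments |
| `sylvasim.management` | threshold detection, four-way classification, calibration |
| `sylvasim.growth` | growth-model fits, mortality, 5-yr-step simulator |
| `sylvasim.scenarios` | BaU and O_v/D/M/A families, mobilization, energy targets |
| `sylvasim.wood_chain` | pathway allocation, product pools, recycling, substitution |
| `sylvasim.carbon` | ledger assembly, carbon efficiency, parity time |
| `sylvasim.synthetic` | ground-truth inventory generator (incl. legacy-stock mode) |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and the limits of what the synthetic fixtures can show.
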