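# Methods

This note documents the models, the numerical choices, and the defaults,
plus what the synthetic fixtures do and do not demonstrate.

## Stand description

Dominant height per species follows a Hossfeld II curve
`h0(age) = a/(1 + (b/age)^c)` fitted by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, start values a=30 m, b=40 yr, c=1.2).  The
site index H100 (dominant height at the 100-yr reference age) transfers
proportionally: assuming the shape parameters are shared across
fertility levels, `H100_plot/h0_plot = H100_guide/h0_guide(age)`.
Fertility classes are equal-probability quantile cuts of the per-species
H100 distribution (linear-interpolation quantiles, default 3 classes —
the class count is a free choice here and configurable).

The self-thinning frontier `log N_max = g + h log Dg` bounds stem number
at a given quadratic mean diameter.  "Fitting an upper envelope" admits
several estimators; the default is quantile regression at τ = 0.99 on
the log-log scale (statsmodels `QuantReg`) followed by OLS through the
points at or above the fitted quantile line, which is robust and
reproducible.  A convex-hull alternative is provided: the line through
the endpoints of the dominant (longest-x) facet of the hull's upper
chain; it serves as an independent cross-check in the tests.  Plots with
ages outside the 10th–90th percentiles are excluded before fitting.
The relative density index is `DI = N / (e^g Dg^h)`.

Stand increments are reconstructed from tree records.  The stem
allometry `v = f(r)` is unspecified beyond monotonicity; a power law
`v = k r^m` fitted on the log-log scale is used (standard allometric
practice; monotone and positive by construction).  The previous-period
radius is `r_{t−5} = ((1−β) r − ir)/(1−β)` with bark ratio β; records
whose reconstructed previous radius is non-positive are excluded and
counted.  The stand volume increment sums `v (1 − f(r_{t−5})/f(r)) · w`
over alive trees of all species; the radius increment averages the
recorded below-bark increments over alive main-species trees only.
Dead trees never enter the increments — mortality is a separate term.

Exploitability is a worst-category-dominates rule over four ordinal
terrain descriptors (slope, ruggedness, distance to ride, carrying
capacity).  The category-to-level table ships as editable YAML
(`sylvasim/data/exploitability_rules.yaml`); the shipped assignments are
package defaults, not measured values.

## Management classification and calibration

Plots are classified in a fixed priority order: (1) exploitability below
the workable floor → unexploitable, (2) Dg above the clearcut diameter
→ harvest-delayed, (3) DI above the density threshold → overstocked,
(4) actively-managed.  Species exceptions (by default *Pinus pinaster*
and *Picea abies*) skip the exploitability and density rules — these
intensively marketed species are managed regardless of terrain and
stocking.

Threshold priors come from a segmented-regression discontinuity: a
two-segment piecewise-constant fit to a fixed-width histogram (2 cm bins
for diameter, 0.05 for DI), breakpoint chosen by an exhaustive SSE scan
over bin edges.  A break is accepted only when the downward step between
segment means exceeds twice the pooled within-segment SD of the bin
counts — a cliff, not the smooth tail of a unimodal distribution;
otherwise the 95th-percentile fallback applies with a warning.

Calibration against reported per-species harvest is deterministic
coordinate descent: the exploitability floor is chosen first over its
four ordinal values (it gates entire stands), then each species' yearly
thinning ratio is bisected in [0, 0.3] until the simulated first-step
harvest matches the report within 5 % relative (within inventory
sampling error).  Clearcut-diameter priors are never calibrated — the
diameter acts on two opposing processes (harvest-delayed assignment and
rotation timing), making its net effect non-monotone.  The historically
calibrated thinning ratios for the three most-adjusted species
(*Q. petraea* 8 %, *P. abies* 11 %, *P. pinaster* 13 %) ship as a named
constant, not recomputed.

## Growth and harvest simulation

Per species, two independent log-linear models with fertility-class
intercepts predict the 5-yr volume and radius increments from DI and
age.  Back-transforming a log model is biased downward by the residual
variance; the smearing correction `exp(σ²/2)` is applied by default and
switchable.  Mortality is a species constant: yearly fraction of
standing volume, estimated as the inventory dead/living volume ratio
divided by the 5-yr census interval (how the census ratio maps to a
yearly rate is a convention of this package).

A step applies, in order: growth, mortality, thinning, clearcut check.
Mortality and thinning compound yearly within the 5-yr step
(`(1−rate)^5`).  Thinning removes volume only — the diameter is not
updated.  The clearcut harvests the entire standing volume once Dg
reaches the species × fertility threshold; the plot is then replaced by
a regrowth stand averaging the young stands (< 10 yr, ≥ 200 stems/ha) of
its species, or a cross-species fallback (6 cm, 5 m³ ha⁻¹ by default —
stands below the 7.5 cm inventory threshold carry little merchantable
volume).  The first five post-harvest years are represented only by
that regrowth state.  DI and H100 are held constant through growth and
replacement, acting as management and fertility proxies; Dg advances by
twice the radius increment.  Volume conservation holds exactly per step:
`V(t+5) = V(t) + IV − mortality − thinned − clearcut`.

Harvest is supply-driven: it depends only on stand state and scenario,
never on demand.  Dead organic matter and soil pools are outside the
model's scope, as are climate feedbacks and disturbances.

Scenario families: O_v thins mobilized overstocked stands, D harvests
mobilized harvest-delayed stands, M lowers the clearcut diameter of
actively-managed stands by 1–10 cm, A combines all three at equal
index.  Mobilization ramps linearly over 30 years to the target area
fraction (10 × intensity %); mobilized plots are chosen largest-diameter
first (D) or densest first (O_v), area-weighted, with a plot-id
tie-break.  Once a mobilized harvest-delayed plot is clearcut it re-
enters actively-managed bookkeeping (a choice of this package; it keeps
the long-horizon equilibrium well defined).  An optional FIFO buffer can
delay the energy accounting of harvested biomass; it is off by default.

## Wood-use chain and carbon balance

Stage 1 allocates harvest to the timber, pulp & industry, and energy
pathways — either by the aggregate national shares (hardwood
16/14/70 %, softwood 53/23/24 %) or by source (softwood: all clearcut
and 26 % of thinnings to timber; hardwood: 57 % of clearcuts, none of
the thinning or coppice wood), the non-timber remainder splitting
between pulp & industry and energy in the aggregate proportion.  The two
routes coincide exactly at the implied reference clearcut share (28 %
hardwood, 36 % softwood).  Stage 2 processes pathways into products:
sawmill efficiency 0.5 sends half the timber pathway to timber
end-products, residues cascading 50/50 to pulp and energy (both
fractions configurable — the intermediate flow fractions of the source
scheme are not published); pulp & industry splits 44 % paper / 56 %
pulp.  Mass is conserved through processing.

Product pools decay exponentially with mean lifetimes: timber 50 yr,
paper 40 yr, energy 1.7 yr, using `stock ← (stock + inflow)·e^(−dt/τ)`.
The printed parameter set gives the paper sub-pool a lifetime but no
substitution coefficient, and the pulp sub-pool a coefficient (0.53) but
no lifetime; both are implemented as printed without inventing the
complements — paper stores carbon and earns no credit, pulp earns credit
and does not store.  Recycling happens once: a configurable fraction of
primary end-of-life (default 50 % of timber and paper) is burnt for
energy, the rest emitted; secondary end-of-life is always emitted.

Substitution is counted against the reference scenario only — the
reference's own substitution line is identically zero by definition.
Extra inflows earn timber 1.2, pulp 0.53, energy 0.5 tC avoided per tC,
against a gas-dominated fossil mix (gas 81 %, oil 15 %, coal 3 %).  All
consecutive uses are credited at harvest time, including the eventual
recycled-energy burn — a deliberate time compression that slightly
front-loads (and mildly overstates) the benefit of timber-bound harvest.

Conversions are package assumptions, fully configurable and flagged as
such: basic density 0.55 (hardwood) / 0.45 (softwood) t dry per m³,
carbon fraction 0.5 tC per t dry, net calorific value 18.5 GJ per t dry,
1 toe = 41.868 GJ — about 0.24 (hardwood) and 0.20 (softwood) toe per
m³ of energy wood.

The ledger tracks, in Tg C on the simulator's 5-yr grid: the in-situ
stock (standing volume × density × carbon fraction × area), the product
stock, and the cumulative substitution credit; their sum is the total
balance.  Carbon efficiency is cumulative total balance divided by
cumulative energy (Mt C per Mtoe; defined from the first step with
positive energy).  Parity time is the first year the scenario's total
balance re-reaches the reference's after having been behind; a scenario
never behind has parity at the start year (no debt was opened), one
never recovering has none.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes,
with analytically known ground truth.  Per plot it draws age (uniform,
plus an old-age excess stratum in legacy mode emulating half a century
of biomass accumulation) and density DI (uniform, with a configurable
fraction exactly on the frontier), then sets the idealized tree radius
to `r = r0 · age^κ · DI^λ · e^ε` with a single lognormal dispersion ε
and a fixed increment fraction `ir = γ(1−β) r`.  All alive trees of a
plot are that tree replicated at equal weights summing to the frontier-
consistent stem count; volumes sit exactly on the allometry.  This
construction makes the reconstructed stand increments *exactly*
log-linear in DI and age, so the growth-model coefficients implied by
(r0, κ, λ, γ, k, m, g, h, β) are closed-form ground truth, and the one
dispersion ε propagates into both models as genuine, perfectly
correlated regression residuals.  Dead records carry five years of
mortality volume, making the mortality estimator exact.  Heights follow
the guide curve scaled by an optional fertility factor with optional
measurement noise.

Defaults describe a plausible temperate stand (e.g. at age 60, DI 0.6:
Dg ≈ 24 cm, N ≈ 440 ha⁻¹, V ≈ 150 m³ ha⁻¹, increment ≈ 3.2 m³ ha⁻¹
yr⁻¹, mortality 0.5 % yr⁻¹).  In legacy mode the management thresholds
recorded as truth are the realized quantiles that carve out the
configured harvest-delayed and overstocked area fractions, so
classification reproduces the configured strata by construction.  The
shipped legacy preset approximates the published national stratum mix
(about 11 % unexploitable, 15 % harvest-delayed, 11 % overstocked).

**What the generator does not emulate** — and hence what green tests do
not show about real data: concentric-subplot sampling geometry and
confidential statistical weights; within-plot size heterogeneity and
species mixtures; age-dependent decline of radial growth (the power-law
radius structure makes both increments *increase* with age, which keeps
the construction exact but means old stands never senesce — one reason
parity times on the fixture run longer than on real inventories);
density-dependent mortality (deliberately absent, as in the source
model); measurement error correlated across variables.  Qualitative
scenario results on the fixture (ordering of in-situ depression, the
overstocked strategy never reaching parity, rotations recovering before
harvest-delayed mobilization) are structural and seed-robust, but the
*numerical* efficiencies, parity years, and mobilized volumes are
fixture properties, not national estimates — the published national
figures depend on the confidential inventory microdata and are not
reproducible at desk scale.

## Problem sizes

Tests and the acceptance script use 400-plot noise-free inventories for
exact recovery, 2000 plots for noisy recovery, 1500–5000 plots for
stratum and scenario runs, and 100-yr horizons (20 steps) for the
scenario comparison; these sizes keep every stage well-conditioned while
the full suite runs in seconds.
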