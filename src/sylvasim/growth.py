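"""Stand-level growth models and the 5-year-step growth-and-harvest simulator.

Growth is empirical: per species, two independent log-linear models
predict the 5-year stand volume increment and the 5-year radius increment
of the idealized average tree from the relative density index, stand age
and a fertility-class intercept::

    log(IV) = a_H100[fert] + a_DI log(DI) + a_age log(age) + eps
    log(Ir) = b_H100[fert] + b_DI log(DI) + b_age log(age) + eps

Because increments rather than states are modelled, the initial volume
and diameter distributions of the inventory are preserved.  Mortality is
a species-specific yearly fraction of standing volume (no density or age
dependence was found in the source data).  The density and fertility
indices of a plot are held constant through growth and after stand
replacement, acting as management and fertility proxies.

A simulation step applies, in order: growth, mortality, thinning (yearly
ratio compounded within the 5-yr step; diameter untouched), and the
clearcut check (the full standing volume is harvested once the quadratic
mean diameter reaches the species × fertility threshold, and the plot is
replaced by its species' regrowth stand).  The wood market is
supply-driven: harvest depends only on stand state and scenario, never on
demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory_io import PlotState, SpeciesTable, TreeRecord, ValidationError
from .management import ManagementThresholds
from .scenarios import ScenarioSpec, mobilization_schedule, select_plots
from .stand_metrics import FitError

__all__ = [
    "GrowthParams",
    "SpeciesGrowth",
    "MortalityRates",
    "RegrowthStand",
    "RegrowthLibrary",
    "Trajectory",
    "fit_growth_models",
    "mortality_rate",
    "predict_increments",
    "step_components",
    "step_plot",
    "apply_thinning",
    "apply_clearcut",
    "build_regrowth_library",
    "run_simulation",
    "make_harvest_evaluator",
]


@dataclass
class SpeciesGrowth:
    """Fitted coefficients of the two log-linear increment models.

    ``a_h100`` / ``b_h100`` map fertility-class label -> intercept (an
    empty-string key serves single-class fits).  ``sigma_iv`` /
    ``sigma_ir`` are residual SDs of the log models, used by the optional
    smearing back-transform exp(sigma^2/2).
    """

    species: str
    a_h100: dict[str, float]
    a_di: float
    a_age: float
    sigma_iv: float
    b_h100: dict[str, float]
    b_di: float
    b_age: float
    sigma_ir: float

    def _intercept(self, table: dict[str, float], fert: str) -> float:
        if fert in table:
            return table[fert]
        if "" in table:
            return table[""]
        raise ValidationError(f"no intercept for fertility class {fert!r}")

    def iv5(self, di: float, age: float, fert: str, smearing: bool = True) -> float:
        """Predicted 5-yr volume increment (m³ ha⁻¹ / 5 yr)."""
        mu = self._intercept(self.a_h100, fert) + self.a_di * np.log(di) + self.a_age * np.log(age)
        corr = 0.5 * self.sigma_iv**2 if smearing else 0.0
        return float(np.exp(mu + corr))

    def ir5(self, di: float, age: float, fert: str, smearing: bool = True) -> float:
        """Predicted 5-yr radius increment of the average tree (m / 5 yr)."""
        mu = self._intercept(self.b_h100, fert) + self.b_di * np.log(di) + self.b_age * np.log(age)
        corr = 0.5 * self.sigma_ir**2 if smearing else 0.0
        return float(np.exp(mu + corr))


@dataclass
class GrowthParams:
    """Per-species growth models plus the smearing switch."""

    species: dict[str, SpeciesGrowth]
    smearing: bool = True

    def for_species(self, name: str) -> SpeciesGrowth:
        try:
            return self.species[name]
        except KeyError:
            raise ValidationError(f"no growth model for species {name!r}") from None


MortalityRates = dict  # species -> yearly fraction of standing volume


def fit_growth_models(
    plot_data: pd.DataFrame, min_plots: int = 30, smearing: bool = True
) -> GrowthParams:
    """Fit both log-linear increment models per species by least squares.

    ``plot_data`` needs columns ``species, fert_class, IV, Ir, DI, age``
    (increments per 5 yr, all positive).  Fertility classes enter as
    separate intercepts (one indicator column per class, no global
    intercept); a species with a single class gets one intercept.
    """
    out: dict[str, SpeciesGrowth] = {}
    for species, df in plot_data.groupby("species"):
        df = df[(df["IV"] > 0) & (df["Ir"] > 0) & (df["DI"] > 0) & (df["age"] > 0)]
        if len(df) < min_plots:
            raise FitError(f"{species}: only {len(df)} usable plots (< {min_plots})")
        classes = sorted(df["fert_class"].astype(str).unique())
        dummies = np.column_stack(
            [(df["fert_class"].astype(str) == c).to_numpy(float) for c in classes]
        )
        X = np.column_stack([dummies, np.log(df["DI"]), np.log(df["age"])])
        coefs = {}
        for yname in ("IV", "Ir"):
            y = np.log(df[yname].to_numpy(float))
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = max(len(y) - X.shape[1], 1)
            coefs[yname] = (beta, float(np.sqrt(resid @ resid / dof)))
        (a, sig_a), (b, sig_b) = coefs["IV"], coefs["Ir"]
        nc = len(classes)
        out[species] = SpeciesGrowth(
            species=species,
            a_h100=dict(zip(classes, map(float, a[:nc]))),
            a_di=float(a[nc]), a_age=float(a[nc + 1]), sigma_iv=sig_a,
            b_h100=dict(zip(classes, map(float, b[:nc]))),
            b_di=float(b[nc]), b_age=float(b[nc + 1]), sigma_ir=sig_b,
        )
    return GrowthParams(out, smearing=smearing)


def mortality_rate(
    trees: Iterable[TreeRecord], census_years: float = 5.0
) -> MortalityRates:
    """Species-specific yearly mortality as dead/living volume ratio.

    Dead records accumulate over the census interval (default 5 yr), so
    the yearly rate is the weighted dead-to-living volume ratio divided
    by ``census_years``.
    """
    dead: dict[str, float] = {}
    living: dict[str, float] = {}
    for t in trees:
        pool = dead if t.status == "dead" else living
        pool[t.species] = pool.get(t.species, 0.0) + t.v_ab * t.w
    rates = {}
    for sp, live in living.items():
        if live <= 0:
            raise ValidationError(f"{sp}: living volume must be > 0")
        rates[sp] = dead.get(sp, 0.0) / live / census_years
    return rates


def predict_increments(
    plot: PlotState, gp: GrowthParams
) -> tuple[float, float]:
    """(IV5 m³ ha⁻¹, Ir5 m) for one plot from the fitted models."""
    sg = gp.for_species(plot.main_species)
    return (
        sg.iv5(plot.DI, plot.age, plot.fert_class, gp.smearing),
        sg.ir5(plot.DI, plot.age, plot.fert_class, gp.smearing),
    )


def step_components(
    plot: PlotState, gp: GrowthParams, mr: Mapping[str, float]
) -> tuple[float, float, float]:
    """(iv5, mortality5, ir5) volume gain, volume lost to mortality, radius gain.

    Mortality compounds yearly on the post-growth volume:
    ``loss = (V + IV) (1 - (1-m)^5)``.
    """
    iv5, ir5 = predict_increments(plot, gp)
    m = mr.get(plot.main_species, 0.0)
    mort5 = (plot.V + iv5) * (1.0 - (1.0 - m) ** 5)
    return iv5, mort5, ir5


def step_plot(plot: PlotState, gp: GrowthParams, mr: Mapping[str, float]) -> PlotState:
    """Advance one plot 5 years: growth and mortality, no management.

    ``V`` gains the modelled increment and loses compounded mortality
    (clipped at zero if mortality exceeds the stock); ``Dg`` grows by
    twice the radius increment; ``age`` advances; ``DI`` and ``H100``
    stay constant as management and fertility proxies.
    """
    if not plot.V > 0:
        raise ValidationError(f"plot {plot.plot_id} has no standing volume")
    iv5, mort5, ir5 = step_components(plot, gp, mr)
    v_new = plot.V + iv5 - mort5
    if v_new < 0:  # mortality exceeded stock; clip and flag
        v_new = 0.0
    return plot.copy(V=v_new, Dg=plot.Dg + 2.0 * ir5 * 100.0, age=plot.age + 5.0)


def apply_thinning(plot: PlotState, ratio: float) -> tuple[PlotState, float]:
    """Remove the yearly thinning ratio, compounded over the 5-yr step.

    ``removed = V (1 - (1 - ratio)^5)``; the diameter is not updated by
    thinning.  Returns (thinned plot, removed volume m³ ha⁻¹).
    """
    if not 0 <= ratio < 1:
        raise ValidationError("thinning ratio must be in [0, 1)")
    removed = plot.V * (1.0 - (1.0 - ratio) ** 5)
    return plot.copy(V=plot.V - removed), removed


@dataclass(frozen=True)
class RegrowthStand:
    """Initial state of a stand in its first simulated post-harvest step."""

    dg0: float  # quadratic mean diameter (cm)
    v0: float  # standing volume (m³ ha⁻¹)
    age0: float = 5.0  # yr; the first 5 post-harvest years are not simulated


@dataclass
class RegrowthLibrary:
    """Per-species regrowth stands plus the cross-species fallback."""

    species: dict[str, RegrowthStand]
    fallback: RegrowthStand

    def for_species(self, name: str) -> RegrowthStand:
        return self.species.get(name, self.fallback)


def build_regrowth_library(
    plots: Sequence[PlotState],
    min_stems: float = 200.0,
    max_age: float = 10.0,
    age0: float = 5.0,
    default_fallback: RegrowthStand | None = None,
) -> RegrowthLibrary:
    """Average young-stand characteristics per species.

    Qualifying stands are younger than ``max_age`` with at least
    ``min_stems`` reconstructed stems per hectare; sparser young stands
    are taken as recently harvested rather than regrowing and excluded.
    Species without qualifying stands fall back to the unweighted mean of
    the per-species entries (or ``default_fallback`` when no species
    qualifies at all).
    """
    young: dict[str, list[PlotState]] = {}
    for p in plots:
        if p.age <= max_age and p.N == p.N and p.N >= min_stems:
            young.setdefault(p.main_species, []).append(p)
    lib = {
        sp: RegrowthStand(
            dg0=float(np.mean([p.Dg for p in ps])),
            v0=float(np.mean([p.V for p in ps])),
            age0=age0,
        )
        for sp, ps in young.items()
    }
    if lib:
        fallback = RegrowthStand(
            dg0=float(np.mean([s.dg0 for s in lib.values()])),
            v0=float(np.mean([s.v0 for s in lib.values()])),
            age0=age0,
        )
    elif default_fallback is not None:
        fallback = default_fallback
    else:
        # below the 7.5 cm inventory threshold young stands carry little
        # merchantable volume
        fallback = RegrowthStand(dg0=6.0, v0=5.0, age0=age0)
    return RegrowthLibrary(lib, fallback)


def apply_clearcut(
    plot: PlotState,
    th: ManagementThresholds,
    lib: RegrowthLibrary,
    diameter_delta: float = 0.0,
) -> tuple[PlotState, float]:
    """Clearcut an eligible plot and install the regrowth stand.

    Eligibility: ``Dg >= clearcut_diameter - diameter_delta`` for the
    plot's species × fertility class.  The whole standing volume becomes
    harvest; the new stand keeps the plot's DI, H100 and area.
    """
    threshold = th.for_species(plot.main_species).clearcut_dg(plot.fert_class) - diameter_delta
    if not plot.Dg >= threshold:
        raise ValidationError(
            f"plot {plot.plot_id}: Dg {plot.Dg:.1f} below clearcut threshold {threshold:.1f}"
        )
    harvested = plot.V
    re = lib.for_species(plot.main_species)
    new = plot.copy(V=re.v0, Dg=re.dg0, age=re.age0)
    return new, harvested


@dataclass
class Trajectory:
    """Output of :func:`run_simulation`.

    ``years`` is the 5-yr time grid (calendar years, including the start
    state).  ``states[k]`` is the list of plot states at ``years[k]``.
    ``harvest`` is a tidy frame of harvest flows with columns
    ``year, plot_id, species, wood_type, source, volume_per_ha, volume_m3``
    (total volume = per-ha × represented area).  ``balance`` records the
    per-step per-plot volume components for conservation checks.
    """

    years: list[float]
    states: list[list[PlotState]]
    harvest: pd.DataFrame
    balance: pd.DataFrame

    def standing_volume_m3(self) -> pd.Series:
        """Total standing volume (m³, area-weighted) per time-grid year."""
        return pd.Series(
            [sum(p.V * p.area for p in st) for st in self.states], index=self.years
        )

    def harvest_by_year(self) -> pd.DataFrame:
        if self.harvest.empty:
            return pd.DataFrame(columns=["year", "source", "wood_type", "volume_m3"])
        return (
            self.harvest.groupby(["year", "source", "wood_type"])["volume_m3"]
            .sum()
            .reset_index()
        )


def _wood_type(species: str, species_table: SpeciesTable | None) -> str:
    if species_table is None:
        return "hardwood"
    return species_table.wood_type(species)


def run_simulation(
    plots: Sequence[PlotState],
    gp: GrowthParams,
    mr: Mapping[str, float],
    th: ManagementThresholds,
    lib: RegrowthLibrary,
    scenario: ScenarioSpec,
    horizon: float,
    species_table: SpeciesTable | None = None,
) -> Trajectory:
    """Run the growth-and-harvest simulation over ``horizon`` years.

    Plots must be classified (``mgmt`` set).  Per 5-yr step and plot:
    growth and mortality always apply (while V > 0); thinning applies to
    actively-managed plots and, under O_v/A scenarios, to mobilized
    overstocked plots; the clearcut check applies to actively-managed and
    overstocked plots (with the M/A diameter reduction for
    actively-managed ones) and to mobilized harvest-delayed plots, which
    are harvested outright and re-enter actively-managed bookkeeping
    afterwards.  Deterministic given its inputs.
    """
    if horizon % 5 != 0:
        raise ValidationError("horizon must be a multiple of 5 years")
    state = [p.copy() for p in plots]
    years = [float(scenario.start_year)]
    states = [state]
    flows: list[dict] = []
    balance: list[dict] = []
    mobilized: set[str] = set()

    n_steps = int(horizon // 5)
    for k in range(n_steps):
        year0 = scenario.start_year + 5 * k
        year1 = year0 + 5
        # mobilization ramp, evaluated on the *initial* classification
        # carried by each plot's current mgmt label
        if scenario.target_fraction > 0:
            frac = mobilization_schedule(
                scenario.target_fraction, year1 - scenario.start_year, scenario.ramp_years
            )
            if scenario.harvests_delayed:
                mobilized |= {p.plot_id for p in select_plots(state, "D", frac)}
            if scenario.thins_overstocked:
                mobilized |= {p.plot_id for p in select_plots(state, "O_v", frac)}
        new_state: list[PlotState] = []
        for p in state:
            rec = {"year": year1, "plot_id": p.plot_id, "V_before": p.V,
                   "iv": 0.0, "mortality": 0.0, "thinned": 0.0, "clearcut": 0.0}
            if p.V > 0:
                iv5, mort5, ir5 = step_components(p, gp, mr)
                mort5 = min(mort5, p.V + iv5)
                p = p.copy(V=p.V + iv5 - mort5, Dg=p.Dg + 2.0 * ir5 * 100.0,
                           age=p.age + 5.0)
                rec["iv"], rec["mortality"] = iv5, mort5
            else:
                p = p.copy(age=p.age + 5.0)
            sp_th = th.for_species(p.main_species)
            is_mob = p.plot_id in mobilized
            thins = p.mgmt == "actively-managed" or (
                p.mgmt == "overstocked" and is_mob and scenario.thins_overstocked
            )
            if thins and sp_th.thinning_ratio > 0 and p.V > 0:
                p, removed = apply_thinning(p, sp_th.thinning_ratio)
                rec["thinned"] = removed
                if removed > 0:
                    flows.append({
                        "year": year1, "plot_id": p.plot_id, "species": p.main_species,
                        "wood_type": _wood_type(p.main_species, species_table),
                        "source": "thinning", "volume_per_ha": removed,
                        "volume_m3": removed * p.area,
                    })
            delta = scenario.diameter_reduction_cm if p.mgmt == "actively-managed" else 0.0
            may_cut = p.mgmt in ("actively-managed", "overstocked") or (
                p.mgmt == "harvest-delayed" and is_mob and scenario.harvests_delayed
            )
            threshold = sp_th.clearcut_dg(p.fert_class) - delta
            if may_cut and p.V > 0 and p.Dg >= threshold:
                source = "coppice" if p.structure == "coppice" else "clearcut"
                p, harvested = apply_clearcut(p, th, lib, diameter_delta=delta)
                rec["clearcut"] = harvested
                flows.append({
                    "year": year1, "plot_id": p.plot_id, "species": p.main_species,
                    "wood_type": _wood_type(p.main_species, species_table),
                    "source": source, "volume_per_ha": harvested,
                    "volume_m3": harvested * p.area,
                })
                if p.mgmt == "harvest-delayed":
                    p = p.copy(mgmt="actively-managed")
            rec["V_after"] = p.V
            balance.append(rec)
            new_state.append(p)
        state = new_state
        years.append(float(year1))
        states.append(state)

    flow_cols = ["year", "plot_id", "species", "wood_type", "source",
                 "volume_per_ha", "volume_m3"]
    return Trajectory(
        years=years,
        states=states,
        harvest=pd.DataFrame(flows, columns=flow_cols),
        balance=pd.DataFrame(balance),
    )


def make_harvest_evaluator(
    gp: GrowthParams,
    mr: Mapping[str, float],
    lib: RegrowthLibrary,
    species_table: SpeciesTable | None = None,
    scenario: ScenarioSpec | None = None,
):
    """Build the ``(plots, thresholds) -> {species: m³ yr⁻¹}`` evaluator
    used by :func:`sylvasim.management.calibrate`.

    Classifies the plots under the candidate thresholds, runs a single
    BaU 5-yr step, and returns per-species yearly harvest.
    """
    from .management import classify

    if scenario is None:
        scenario = ScenarioSpec("BaU")

    def evaluate(plots: Sequence[PlotState], th: ManagementThresholds) -> dict[str, float]:
        classified = classify(plots, th)
        traj = run_simulation(classified, gp, mr, th, lib, scenario, 5.0, species_table)
        if traj.harvest.empty:
            return {}
        per_species = traj.harvest.groupby("species")["volume_m3"].sum() / 5.0
        return per_species.to_dict()

    return evaluate
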