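"""Synthetic inventory generator with known ground truth.

Generates plot and tree tables carrying the statistical structure the
analysis pipeline assumes — a Hossfeld height-age guide curve, a log-log
self-thinning frontier, power-law stem allometry, log-linear increment
models, species bark and mortality ratios — so that every estimator in
the pipeline can be checked against configured truth, without access to
any real inventory.

Construction
------------
Per plot: age and relative density DI are drawn; the radius of the
idealized tree follows ``r = r0 · age^kappa · DI^lambda · e^eps`` with
lognormal dispersion ``eps ~ N(0, sigma_r²)``, and every alive tree in
the plot is that idealized tree, replicated with equal weights summing
to ``N = DI e^g Dg^h`` (on-frontier plots have DI = 1 exactly).  The
below-bark radius increment is a fixed fraction of the radius,
``ir = gamma (1 - beta) r``, and tree volumes sit exactly on the
allometry ``v = k r^m``.  This makes the stand-level increments that the
pipeline reconstructs from the trees *exactly* log-linear in DI and age::

    log IV = a0 + (1 + lambda (m + h)) log DI + kappa (m + h) log age + (m + h) eps
    log Ir = b0 + lambda log DI + kappa log age + eps

with ``a0 = log(e^g 200^h k (1 - (1 - gamma)^m) r0^(m+h))`` and
``b0 = log(gamma (1 - beta) r0)`` — the derived coefficients are the
known ground truth the recovery tests target, and the single dispersion
``sigma_r`` propagates into both models (perfectly correlated residuals,
a deliberate simplification).  Dominant height follows the guide curve
scaled by a per-plot fertility factor; dead trees are planted so the
species dead/living volume ratio equals ``5 × mortality`` exactly.

A legacy-stock mode adds an old-age excess stratum (the accumulated
biomass of decades of under-harvesting) and places the clearcut-diameter
and density thresholds at the realized quantiles that carve out the
configured harvest-delayed and overstocked area fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .inventory_io import EXPLOIT_LEVELS, PlotState, TreeRecord, ValidationError
from .management import ManagementThresholds, SpeciesThresholds
from .stand_metrics import GuideCurve, SelfThinning, VolumeRadiusFit

__all__ = [
    "SpeciesParams",
    "GeneratorConfig",
    "InventoryTruth",
    "generate_inventory",
    "legacy_stock_inventory",
    "noise_free_config",
    "legacy_config",
]


@dataclass(frozen=True)
class SpeciesParams:
    """Ground-truth parameters of one synthetic species."""

    name: str
    wood_type: str = "hardwood"
    # guide curve h0 = a / (1 + (b/age)^c)
    guide_a: float = 30.0
    guide_b: float = 40.0
    guide_c: float = 1.2
    # self-thinning frontier log N = g + h log Dg
    st_g: float = 12.0
    st_h: float = -1.7
    beta: float = 0.1  # bark fraction of above-bark radius
    vr_k: float = 55.0  # stem allometry v = k r^m  (r in m, v in m³)
    vr_m: float = 2.4
    # radius structure r = r0 age^kappa DI^lambda
    r0: float = 0.0093
    kappa: float = 0.6
    lam: float = -0.2
    gamma: float = 0.046  # above-bark increment as a fraction of radius
    mortality: float = 0.005  # yearly fraction of standing volume

    # ----- derived ground-truth growth-model coefficients ----------------
    @property
    def b_intercept(self) -> float:
        return float(np.log(self.gamma * (1 - self.beta) * self.r0))

    @property
    def b_di(self) -> float:
        return self.lam

    @property
    def b_age(self) -> float:
        return self.kappa

    @property
    def a_intercept(self) -> float:
        mph = self.vr_m + self.st_h
        return float(
            self.st_g + self.st_h * np.log(200.0) + np.log(self.vr_k)
            + np.log(1.0 - (1.0 - self.gamma) ** self.vr_m)
            + mph * np.log(self.r0)
        )

    @property
    def a_di(self) -> float:
        return 1.0 + self.lam * (self.vr_m + self.st_h)

    @property
    def a_age(self) -> float:
        return self.kappa * (self.vr_m + self.st_h)

    def guide(self) -> GuideCurve:
        return GuideCurve(self.name, self.guide_a, self.guide_b, self.guide_c)

    def self_thinning(self) -> SelfThinning:
        return SelfThinning(self.name, self.st_g, self.st_h)

    def volume_radius(self) -> VolumeRadiusFit:
        return VolumeRadiusFit(self.name, self.vr_k, self.vr_m)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic inventory.

    ``sigma_r`` is the lognormal dispersion of the idealized-tree radius
    (it propagates into both increment models); ``h0_sd`` additive normal
    noise on dominant height (m); ``fert_spread_sd`` lognormal spread of
    the per-plot site index around the guide (0 = single fertility).
    ``frontier_fraction`` of plots sit exactly on the self-thinning
    frontier (DI = 1).  ``exploit_probs`` are the probabilities of the
    four exploitability levels, best to worst.  In legacy mode,
    ``legacy_fraction`` of plots draw their age from the old-age range
    and ``frac_over_diameter`` / ``frac_over_density`` fix the
    harvest-delayed and overstocked area shares by quantile thresholds.
    """

    seed: int = 0
    n_plots: int = 500
    species: tuple[SpeciesParams, ...] = (SpeciesParams("Fagus sylvatica"),)
    species_probs: tuple[float, ...] | None = None
    n_regions: int = 3
    trees_per_plot: int = 6
    plot_area_ha: float = 100.0
    age_range: tuple[float, float] = (20.0, 120.0)
    legacy_fraction: float = 0.0
    legacy_age_range: tuple[float, float] = (120.0, 200.0)
    di_range: tuple[float, float] = (0.3, 0.95)
    frontier_fraction: float = 0.05
    sigma_r: float = 0.0
    h0_sd: float = 0.0
    fert_spread_sd: float = 0.0
    coppice_fraction: float = 0.0
    exploit_probs: tuple[float, float, float, float] = (0.25, 0.40, 0.24, 0.11)
    frac_over_diameter: float = 0.15
    frac_over_density: float = 0.11

    def __post_init__(self) -> None:
        if self.n_plots <= 0:
            raise ValidationError("n_plots must be > 0")
        if abs(sum(self.exploit_probs) - 1.0) > 1e-9:
            raise ValidationError("exploitability probabilities must sum to 1")
        if self.species_probs is not None:
            if len(self.species_probs) != len(self.species):
                raise ValidationError("species_probs length mismatch")
            if abs(sum(self.species_probs) - 1.0) > 1e-9:
                raise ValidationError("species probabilities must sum to 1")
        if not 0 < self.di_range[0] <= self.di_range[1] <= 1.2:
            raise ValidationError("DI range must lie within (0, 1.2]")
        for sp in self.species:
            if not 0 < sp.gamma < 1:
                raise ValidationError(f"{sp.name}: gamma must be in (0, 1)")
            if not 0 <= sp.beta < 1:
                raise ValidationError(f"{sp.name}: bark ratio must be in [0, 1)")
            if sp.vr_m + sp.st_h <= 0:
                raise ValidationError(
                    f"{sp.name}: allometry and frontier slopes give a "
                    "non-increasing volume-diameter structure"
                )


@dataclass
class InventoryTruth:
    """Ground truth record written alongside a generated inventory."""

    species: dict[str, SpeciesParams]
    thresholds: ManagementThresholds | None
    stratum_fractions: dict[str, float]
    config: GeneratorConfig


def _draw_exploit(rng: np.random.Generator, probs) -> str:
    return EXPLOIT_LEVELS[rng.choice(4, p=np.asarray(probs, dtype=float))]


def generate_inventory(
    cfg: GeneratorConfig,
) -> tuple[list[PlotState], dict[str, list[TreeRecord]], InventoryTruth]:
    """Generate (plot list, trees by plot, truth record); same seed, same output."""
    rng = np.random.default_rng(cfg.seed)
    by_name = {sp.name: sp for sp in cfg.species}
    probs = cfg.species_probs or tuple(1 / len(cfg.species) for _ in cfg.species)
    plots: list[PlotState] = []
    trees: dict[str, list[TreeRecord]] = {}
    for i in range(cfg.n_plots):
        sp = cfg.species[rng.choice(len(cfg.species), p=np.asarray(probs, float))]
        plot_id = f"P{i:05d}"
        # age, with optional legacy old-age excess
        if cfg.legacy_fraction > 0 and rng.random() < cfg.legacy_fraction:
            age = rng.uniform(*cfg.legacy_age_range)
        else:
            age = rng.uniform(*cfg.age_range)
        di = 1.0 if rng.random() < cfg.frontier_fraction else rng.uniform(*cfg.di_range)
        eps = rng.normal(0.0, cfg.sigma_r) if cfg.sigma_r > 0 else 0.0
        r = sp.r0 * age**sp.kappa * di**sp.lam * np.exp(eps)
        dg = 200.0 * r
        n_stems = di * np.exp(sp.st_g) * dg**sp.st_h
        v_tree = sp.vr_k * r**sp.vr_m
        ir = sp.gamma * (1.0 - sp.beta) * r
        v_stand = n_stems * v_tree
        # dominant height from the guide, scaled by a fertility factor
        fert = np.exp(rng.normal(0.0, cfg.fert_spread_sd)) if cfg.fert_spread_sd > 0 else 1.0
        guide = sp.guide()
        h0 = fert * float(guide.h0(age))
        if cfg.h0_sd > 0:
            h0 = max(h0 + rng.normal(0.0, cfg.h0_sd), 0.5)
        h100 = fert * guide.H100
        structure = "coppice" if rng.random() < cfg.coppice_fraction else "high-stand"
        exploit = _draw_exploit(rng, cfg.exploit_probs)
        plots.append(PlotState(
            plot_id=plot_id, region=f"R{i % cfg.n_regions}", main_species=sp.name,
            structure=structure, age=float(age), h0=float(h0), V=float(v_stand),
            Dg=float(dg), N=float(n_stems), DI=float(di), H100=float(h100),
            fert_class="", exploit=exploit, area=cfg.plot_area_ha,
        ))
        w = n_stems / cfg.trees_per_plot
        recs = [
            TreeRecord(
                tree_id=f"{plot_id}T{j}", species=sp.name, r_ab=float(r),
                ir_bb=float(ir), v_ab=float(v_tree), w=float(w), status="alive",
            )
            for j in range(cfg.trees_per_plot)
        ]
        # one dead record carrying 5 yr of mortality volume (dead/living = 5m)
        if sp.mortality > 0:
            recs.append(TreeRecord(
                tree_id=f"{plot_id}D0", species=sp.name, r_ab=float(r),
                ir_bb=0.0, v_ab=float(5.0 * sp.mortality * v_stand), w=1.0,
                status="dead",
            ))
        trees[plot_id] = recs
    truth = InventoryTruth(by_name, None, {}, cfg)
    return plots, trees, truth


def _quantile_thresholds(
    plots: list[PlotState], cfg: GeneratorConfig
) -> ManagementThresholds:
    """Thresholds carving the configured strata out of the realized inventory.

    Applied in classification priority order: the clearcut-diameter
    threshold is the (1 - frac_over_diameter) quantile of Dg among
    exploitable plots, the DI threshold the (1 - frac_over_density)
    quantile of DI among exploitable plots at or below that diameter.
    """
    species_th: dict[str, SpeciesThresholds] = {}
    for name in {p.main_species for p in plots}:
        mine = [p for p in plots if p.main_species == name]
        workable = [p for p in mine if p.exploit != "impossible"]
        if not workable:
            workable = mine
        dgs = np.array([p.Dg for p in workable])
        dg_th = float(np.quantile(dgs, 1.0 - cfg.frac_over_diameter))
        under = [p for p in workable if p.Dg <= dg_th]
        dis = np.array([p.DI for p in under] or [1.0])
        di_th = float(np.quantile(dis, 1.0 - cfg.frac_over_density))
        species_th[name] = SpeciesThresholds(
            clearcut_diameter={"": max(dg_th, 7.6)}, di_threshold=di_th,
        )
    return ManagementThresholds(species_th, exploitability_floor="difficult")


def legacy_stock_inventory(
    cfg: GeneratorConfig,
) -> tuple[list[PlotState], dict[str, list[TreeRecord]], InventoryTruth]:
    """Inventory with over-mature / over-dense strata and matching thresholds.

    The truth record carries thresholds under which classification
    reproduces the configured stratum fractions (harvest-delayed and
    overstocked among exploitable plots) up to quantile granularity.
    """
    if cfg.legacy_fraction <= 0:
        raise ValidationError("legacy mode needs legacy_fraction > 0")
    plots, trees, truth = generate_inventory(cfg)
    th = _quantile_thresholds(plots, cfg)
    n = len(plots)
    truth.thresholds = th
    n_unexp = sum(p.exploit == "impossible" for p in plots)
    truth.stratum_fractions = {
        "unexploitable": n_unexp / n,
        "harvest-delayed": cfg.frac_over_diameter * (1 - n_unexp / n),
        "overstocked": cfg.frac_over_density * (1 - cfg.frac_over_diameter) * (1 - n_unexp / n),
    }
    return plots, trees, truth


def noise_free_config(seed: int = 0, n_plots: int = 400) -> GeneratorConfig:
    """Noise-free single-species configuration for exact-recovery tests."""
    return GeneratorConfig(seed=seed, n_plots=n_plots)


def legacy_config(seed: int = 0, n_plots: int = 2000) -> GeneratorConfig:
    """National-mix-flavoured legacy-stock configuration.

    Old-age excess emulating half a century of biomass build-up, with
    exploitability and stratum shares near the published national
    classification (about 11 % unexploitable, 15 % harvest-delayed,
    11 % overstocked of the total).
    """
    hardwood = SpeciesParams("Quercus petraea", wood_type="hardwood")
    softwood = SpeciesParams(
        "Picea abies", wood_type="softwood", guide_a=38.0, guide_b=35.0,
        guide_c=1.3, st_g=12.4, st_h=-1.75, beta=0.08, vr_k=48.0, vr_m=2.35,
        r0=0.0105, kappa=0.62, lam=-0.18, gamma=0.055, mortality=0.004,
    )
    return GeneratorConfig(
        seed=seed, n_plots=n_plots, species=(hardwood, softwood),
        species_probs=(0.6, 0.4), legacy_fraction=0.2,
        exploit_probs=(0.25, 0.40, 0.24, 0.11),
        frac_over_diameter=0.17, frac_over_density=0.15,
        sigma_r=0.0,
    )
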