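"""The reconstructed national wood-use chain.

Harvested commercial volume first enters one of three pathways — timber,
pulp & industry, and energy — either by the aggregate per-wood-type
shares (hardwood 16/14/70 %, softwood 53/23/24 % of the harvest) or by
source: harvest from high-stand clearcuts is preferentially used as
timber (softwood: all clearcut and 26 % of thinnings; hardwood: 57 % of
clearcuts, no thinning or coppice wood), the remainder splitting between
pulp & industry and energy in the wood type's aggregate proportion.  The
two routes coincide at the implied reference clearcut share of the
national harvest.

Processing then turns pathways into products: the sawmill converts about
half of the timber pathway into timber end-products, the sawing residues
cascading to the pulp and energy products; the pulp & industry total
splits into a paper sub-pool (44 %) and a pulp sub-pool (56 %).  Product
pools store carbon with first-order decay
at their mean lifetimes (timber 50 yr, paper 40 yr, energy 1.7 yr); the
pulp sub-pool carries no printed lifetime and is treated as immediate
release.  Substitution credits (timber 1.2, pulp 0.53, energy
0.5 tC avoided per tC, against a gas-dominated fossil mix) apply to the
*extra* flows of a scenario relative to the reference scenario, all
credited at harvest time — including the energy from the single permitted
recycling of end-of-life products (a deliberate time compression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inventory_io import ValidationError

__all__ = [
    "AllocationRules",
    "ProductPool",
    "EnergyMix",
    "RecyclingScheme",
    "WoodChainConfig",
    "allocate_harvest",
    "split_pulp_paper",
    "update_product_pools",
    "recycle",
    "substitution_savings",
    "substitution_credit",
    "energy_production",
    "volume_to_carbon",
    "run_wood_chain",
]

PRODUCTS = ("timber", "pulp_industry", "energy")
SOURCES = ("thinning", "clearcut", "coppice")
WOOD_TYPES = ("hardwood", "softwood")

# printed aggregate allocation of the national harvest (fractions of
# commercial volume to timber / pulp & industry / energy)
DEFAULT_AGGREGATE = {
    "hardwood": {"timber": 0.16, "pulp_industry": 0.14, "energy": 0.70},
    "softwood": {"timber": 0.53, "pulp_industry": 0.23, "energy": 0.24},
}
# fraction of each source entering the timber pathway (stage 1)
DEFAULT_TIMBER_PATHWAY = {
    "hardwood": {"clearcut": 0.57, "thinning": 0.0, "coppice": 0.0},
    "softwood": {"clearcut": 1.0, "thinning": 0.26, "coppice": 0.26},
}
PULP_PAPER_SPLIT = {"paper": 0.44, "pulp": 0.56}


@dataclass(frozen=True)
class AllocationRules:
    """Allocation of harvested volume to the three wood-use pathways.

    ``aggregate[wood_type][pathway]`` are the per-wood-type shares of the
    harvest entering each pathway.  ``timber_pathway[wood_type][source]``
    is the by-source split: harvest from high-stand clearcuts is
    preferentially used as timber, thinning and coppice wood goes to pulp
    and energy.  The non-timber part splits between the pulp & industry
    and energy pathways by ``rho = f_pulp / (f_pulp + f_energy)`` so that
    the by-source route integrates back to the aggregates at the implied
    reference clearcut share ``c = (f_timber - p_thin) / (p_cc - p_thin)``.
    """

    aggregate: Mapping[str, Mapping[str, float]]
    timber_pathway: Mapping[str, Mapping[str, float]]
    rho: Mapping[str, float]

    def __post_init__(self) -> None:
        for wt, fracs in self.aggregate.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{wt}: aggregate fractions sum to {total}, not 1")
            if any(not 0 <= f <= 1 for f in fracs.values()):
                raise ValidationError(f"{wt}: fractions outside [0, 1]")

    @classmethod
    def default(
        cls,
        aggregate: Mapping[str, Mapping[str, float]] | None = None,
        timber_pathway: Mapping[str, Mapping[str, float]] | None = None,
    ) -> "AllocationRules":
        aggregate = aggregate or DEFAULT_AGGREGATE
        timber_pathway = timber_pathway or DEFAULT_TIMBER_PATHWAY
        rho = {}
        for wt in aggregate:
            f_p = aggregate[wt]["pulp_industry"]
            f_e = aggregate[wt]["energy"]
            rho[wt] = f_p / (f_p + f_e)
        return cls(aggregate, timber_pathway, rho)

    def reference_clearcut_share(self, wood_type: str) -> float:
        """Clearcut share of the harvest at which by-source equals aggregate."""
        p = self.timber_pathway[wood_type]
        f_t = self.aggregate[wood_type]["timber"]
        return (f_t - p["thinning"]) / (p["clearcut"] - p["thinning"])


def allocate_harvest(
    volume_m3: float,
    wood_type: str,
    rules: AllocationRules,
    source: str | None = None,
) -> dict[str, float]:
    """Split a harvest flow into timber / pulp & industry / energy pathways.

    Without a ``source`` the aggregate per-wood-type fractions apply
    directly.  With a source, the timber-pathway share of that source
    applies first and the remainder splits between the pulp & industry
    and energy pathways by the wood type's ``rho``.
    """
    if volume_m3 < 0:
        raise ValidationError("harvest volume must be >= 0")
    if wood_type not in rules.aggregate:
        raise ValidationError(f"unknown wood type {wood_type!r}")
    if source is None:
        return {p: volume_m3 * rules.aggregate[wood_type][p] for p in PRODUCTS}
    if source not in SOURCES:
        raise ValidationError(f"unknown source {source!r}")
    t_path = volume_m3 * rules.timber_pathway[wood_type][source]
    pe_path = volume_m3 - t_path
    rho = rules.rho[wood_type]
    return {
        "timber": t_path,
        "pulp_industry": pe_path * rho,
        "energy": pe_path * (1.0 - rho),
    }


def process_pathways(
    pathways: Mapping[str, float],
    sawmill_efficiency: float = 0.5,
    residue_to_pulp: float = 0.5,
    pulp_paper_split: Mapping[str, float] = PULP_PAPER_SPLIT,
) -> dict[str, float]:
    """Transform pathway volumes into final product volumes.

    Of the timber pathway, ``sawmill_efficiency`` becomes timber
    end-product; sawing residues cascade to the pulp & industry and
    energy products (``residue_to_pulp`` of them to pulp).  The pulp &
    industry total then splits into the paper and pulp sub-pools; the
    energy pathway burns as energy wood.  Mass is conserved exactly.
    """
    if not 0 < sawmill_efficiency <= 1:
        raise ValidationError("sawmill efficiency must be in (0, 1]")
    if not 0 <= residue_to_pulp <= 1:
        raise ValidationError("residue split must be in [0, 1]")
    timber = pathways["timber"] * sawmill_efficiency
    residues = pathways["timber"] - timber
    pulp_industry = pathways["pulp_industry"] + residues * residue_to_pulp
    energy = pathways["energy"] + residues * (1.0 - residue_to_pulp)
    pp = split_pulp_paper(pulp_industry, pulp_paper_split)
    return {"timber": timber, "paper": pp["paper"], "pulp": pp["pulp"], "energy": energy}


def split_pulp_paper(pulp_industry: float,
                     split: Mapping[str, float] = PULP_PAPER_SPLIT) -> dict[str, float]:
    """Split the pulp & industry product into paper and pulp sub-pools."""
    return {k: pulp_industry * v for k, v in split.items()}


@dataclass
class ProductPool:
    """One wood-product carbon pool with first-order decay.

    ``lifetime`` is the mean life expectancy in years; ``None`` means the
    pool does not store (inflow passes straight through).  ``substitution``
    is tC of fossil emission avoided per tC of extra product.
    """

    product: str
    lifetime: float | None
    substitution: float
    stock: float = 0.0  # tC

    def __post_init__(self) -> None:
        if self.lifetime is not None and not self.lifetime > 0:
            raise ValidationError("lifetime must be > 0 (or None for pass-through)")
        if self.stock < 0:
            raise ValidationError("stock must be >= 0")


def default_pools() -> dict[str, ProductPool]:
    """Pools with the printed lifetimes and substitution coefficients.

    The paper sub-pool has a printed lifetime but no substitution
    coefficient (credited 0); the pulp sub-pool has a printed coefficient
    but no lifetime (no storage).
    """
    return {
        "timber": ProductPool("timber", 50.0, 1.2),
        "paper": ProductPool("paper", 40.0, 0.0),
        "pulp": ProductPool("pulp", None, 0.53),
        "energy": ProductPool("energy", 1.7, 0.5),
    }


@dataclass(frozen=True)
class EnergyMix:
    """Fossil carriers displaced by wood energy (shares of substitution)."""

    shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "gas": 0.81, "oil": 0.15, "coal": 0.03, "electricity": 0.004, "gpl": 0.004,
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if abs(total - 1.0) > 0.02:
            raise ValidationError(f"energy-mix shares sum to {total}, expected ~1")


@dataclass(frozen=True)
class RecyclingScheme:
    """Routing of primary end-of-life flows (single recycling).

    ``to_energy[product]`` is the fraction of the product's first-use
    end-of-life that is burnt for energy as a second use; the remainder
    is emitted directly.  Secondary end-of-life is always fully emitted.
    """

    to_energy: Mapping[str, float] = field(
        default_factory=lambda: {"timber": 0.5, "paper": 0.5, "pulp": 0.0, "energy": 0.0}
    )

    def __post_init__(self) -> None:
        for p, f in self.to_energy.items():
            if not 0 <= f <= 1:
                raise ValidationError(f"{p}: recycling fraction outside [0, 1]")


def update_product_pools(
    pools: Mapping[str, ProductPool], inflow_tc: Mapping[str, float], dt: float
) -> tuple[dict[str, ProductPool], dict[str, float]]:
    """Advance the pools by ``dt`` years with exponential decay.

    ``stock' = (stock + inflow) exp(-dt / lifetime)``; the decayed amount
    is the end-of-life outflow, to be routed by :func:`recycle`.
    Pass-through pools (no lifetime) release everything.
    """
    if dt < 0:
        raise ValidationError("dt must be >= 0")
    new_pools: dict[str, ProductPool] = {}
    outflow: dict[str, float] = {}
    for name, pool in pools.items():
        total = pool.stock + inflow_tc.get(name, 0.0)
        if pool.lifetime is None:
            remaining = 0.0 if dt > 0 else total
        else:
            remaining = total * float(np.exp(-dt / pool.lifetime))
        new_pools[name] = ProductPool(pool.product, pool.lifetime, pool.substitution,
                                      remaining)
        outflow[name] = total - remaining
    return new_pools, outflow


def recycle(
    end_of_life_tc: Mapping[str, float],
    scheme: RecyclingScheme,
    generation: str = "primary",
) -> tuple[dict[str, float], float]:
    """Route end-of-life flows: (energy burn tC, direct emission tC).

    Only primary (first-use) flows may be recycled, and only once;
    secondary flows are fully emitted.  Flows must be tagged with their
    use generation.
    """
    if generation not in ("primary", "secondary"):
        raise ValidationError(f"unknown use generation {generation!r}")
    if generation == "secondary":
        return {p: 0.0 for p in end_of_life_tc}, sum(end_of_life_tc.values())
    burned: dict[str, float] = {}
    emitted = 0.0
    for product, amount in end_of_life_tc.items():
        f = scheme.to_energy.get(product, 0.0)
        burned[product] = amount * f
        emitted += amount * (1.0 - f)
    return burned, emitted


def substitution_credit(
    inflow_tc: Mapping[str, float],
    pools: Mapping[str, ProductPool],
    scheme: RecyclingScheme,
) -> float:
    """Avoided fossil emission (tC) earned by one step's product inflows.

    Every consecutive use is credited at harvest time: the first-use
    product earns its own coefficient, and the fraction destined for the
    single recycling into energy earns the energy coefficient on top.
    """
    credit = 0.0
    energy_coef = pools["energy"].substitution
    for product, amount in inflow_tc.items():
        credit += amount * pools[product].substitution
        if product != "energy":
            credit += amount * scheme.to_energy.get(product, 0.0) * energy_coef
    return credit


def substitution_savings(
    scenario_inflows: pd.DataFrame,
    bau_inflows: pd.DataFrame,
    pools: Mapping[str, ProductPool] | None = None,
    scheme: RecyclingScheme | None = None,
) -> pd.Series:
    """Per-step apparent-stock increments (tC) of a scenario versus BaU.

    Both frames are indexed by year with one column per product carrying
    tC inflows.  The credit is the product-wise difference multiplied by
    the substitution coefficients (with the recycled-energy top-up),
    credited at the harvest step.  Antisymmetric under exchanging the two
    series; identically zero when they coincide.
    """
    pools = pools or default_pools()
    scheme = scheme or RecyclingScheme()
    if not scenario_inflows.index.equals(bau_inflows.index):
        raise ValidationError("scenario and BaU inflow series must share the time grid")
    delta = scenario_inflows.sub(bau_inflows, fill_value=0.0)
    return delta.apply(
        lambda row: substitution_credit(row.to_dict(), pools, scheme), axis=1
    )


GJ_PER_TOE = 41.868


@dataclass(frozen=True)
class WoodChainConfig:
    """Conversion constants and component configurations of the chain.

    Densities are basic wood density (t dry matter per m³ of commercial
    volume); carbon content is tC per t dry matter; ``ncv_gj_per_t`` the
    net calorific value of dry wood.  All are assumptions of this package
    (the chain's sources report volumes and shares, not factors) and are
    fully configurable.
    """

    rules: AllocationRules = field(default_factory=AllocationRules.default)
    scheme: RecyclingScheme = field(default_factory=RecyclingScheme)
    density: Mapping[str, float] = field(
        default_factory=lambda: {"hardwood": 0.55, "softwood": 0.45}
    )
    carbon_fraction: float = 0.5
    ncv_gj_per_t: float = 18.5
    sawmill_efficiency: float = 0.5
    residue_to_pulp: float = 0.5
    pulp_paper_split: Mapping[str, float] = field(default_factory=lambda: dict(PULP_PAPER_SPLIT))

    def toe_per_m3(self, wood_type: str) -> float:
        return self.density[wood_type] * self.ncv_gj_per_t / GJ_PER_TOE

    def toe_per_tc(self) -> float:
        return self.ncv_gj_per_t / self.carbon_fraction / GJ_PER_TOE


def volume_to_carbon(volume_m3: float, wood_type: str, cfg: WoodChainConfig) -> float:
    """Commercial volume (m³) to carbon mass (tC)."""
    return volume_m3 * cfg.density[wood_type] * cfg.carbon_fraction


def energy_production(energy_volume_m3: Mapping[str, float] | float,
                      cfg: WoodChainConfig,
                      wood_type: str = "hardwood") -> float:
    """Primary energy (Mtoe) from energy-pathway volumes.

    Accepts either a single volume with its wood type or a mapping
    ``wood_type -> m³``.
    """
    if isinstance(energy_volume_m3, (int, float)):
        energy_volume_m3 = {wood_type: float(energy_volume_m3)}
    toe = sum(v * cfg.toe_per_m3(wt) for wt, v in energy_volume_m3.items())
    return toe / 1e6


def run_wood_chain(
    harvest: pd.DataFrame,
    years: Sequence[float],
    cfg: WoodChainConfig | None = None,
    by_source: bool = True,
) -> pd.DataFrame:
    """Route a harvest-flow table through the chain over a 5-yr time grid.

    ``harvest`` is the tidy flow frame of a simulation trajectory
    (columns ``year, wood_type, source, volume_m3``); ``years`` the full
    grid including the start year (no flows).  Returns a frame indexed by
    year with product inflows (tC), pool stocks (tC), direct emissions
    (tC, cumulative closure: inflow = stock change + emissions), energy
    production from the harvest step and from end-of-life burning (Mtoe
    per step), and the harvest-time substitution-creditable inflow table.
    """
    cfg = cfg or WoodChainConfig()
    pools = default_pools()
    scheme = cfg.scheme
    years = list(years)
    rows = []
    # pending secondary energy stock: burnt at EOL, emitted the same step
    for i, year in enumerate(years):
        dt = years[i] - years[i - 1] if i > 0 else 0.0
        step_flows = harvest[harvest["year"] == year] if not harvest.empty else harvest
        inflow_tc = {p: 0.0 for p in ("timber", "paper", "pulp", "energy")}
        energy_m3: dict[str, float] = {}
        for f in step_flows.itertuples(index=False):
            pathways = allocate_harvest(
                f.volume_m3, f.wood_type, cfg.rules,
                source=(f.source if by_source else None),
            )
            products = process_pathways(
                pathways, cfg.sawmill_efficiency, cfg.residue_to_pulp,
                cfg.pulp_paper_split,
            )
            for product, vol in products.items():
                inflow_tc[product] += volume_to_carbon(vol, f.wood_type, cfg)
            energy_m3[f.wood_type] = energy_m3.get(f.wood_type, 0.0) + products["energy"]
        # decay existing stocks and add this step's inflows
        pools, eol = update_product_pools(pools, inflow_tc, dt)
        burned, emitted = recycle(eol, scheme, generation="primary")
        secondary_energy_tc = sum(burned.values())
        # the single second use is burning: emitted the same step
        emitted += secondary_energy_tc
        energy_step = energy_production(energy_m3, cfg) + secondary_energy_tc * cfg.toe_per_tc() / 1e6
        credit = substitution_credit(inflow_tc, pools, scheme)
        rows.append({
            "year": year,
            **{f"inflow_{p}_tC": v for p, v in inflow_tc.items()},
            **{f"stock_{p}_tC": pool.stock for p, pool in pools.items()},
            "emission_tC": emitted,
            "secondary_energy_tC": secondary_energy_tc,
            "energy_Mtoe": energy_step,
            "substitution_creditable_tC": credit,
        })
    out = pd.DataFrame(rows).set_index("year")
    out["stock_total_tC"] = out[[f"stock_{p}_tC" for p in ("timber", "paper", "pulp", "energy")]].sum(axis=1)
    return out
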