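"""Three-component carbon balance, carbon efficiency, and parity time.

The forest-sector balance at each 5-yr step is the sum of

* the **in-situ** carbon stock of standing biomass (Tg C),
* the **product** carbon stock held in wood-product pools (Tg C), and
* the cumulative **substitution** apparent stock: fossil emissions
  avoided by the scenario's extra wood products and energy relative to
  the reference scenario (Tg C; identically zero for the reference
  itself, by definition).

The carbon efficiency of bioenergy is the cumulative total balance
divided by cumulative energy production (Mt C per Mtoe; 1 Mt C = 1 Tg C).
The carbon parity time of an intensification scenario is the first year
its cumulative total balance catches up with the reference after having
been behind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import Trajectory
from .inventory_io import SpeciesTable, ValidationError
from .wood_chain import WoodChainConfig, volume_to_carbon

__all__ = [
    "CarbonLedger",
    "in_situ_stock",
    "assemble_ledger",
    "carbon_efficiency",
    "parity_time",
    "run_scenario_ledgers",
]

TC_PER_TG = 1e6


@dataclass
class CarbonLedger:
    """Time series of the carbon-balance components.

    ``frame`` is indexed by year with columns ``in_situ``, ``products``,
    ``substitution`` (all Tg C; substitution cumulative), ``total`` (their
    sum), ``energy_annual`` and ``energy_cum`` (Mtoe).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        comp = self.frame[["in_situ", "products", "substitution"]].sum(axis=1)
        if not np.allclose(comp, self.frame["total"], rtol=0, atol=1e-9 * max(1.0, comp.abs().max())):
            raise ValidationError("total must equal in_situ + products + substitution")

    @property
    def years(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=float)

    def cumulative_total(self) -> pd.Series:
        return self.frame["total"]


def in_situ_stock(
    traj: Trajectory, species_table: SpeciesTable | None, cfg: WoodChainConfig
) -> pd.Series:
    """Standing-biomass carbon (Tg C) per time-grid year of a trajectory."""
    values = []
    for state in traj.states:
        tc = 0.0
        for p in state:
            wt = species_table.wood_type(p.main_species) if species_table else "hardwood"
            tc += volume_to_carbon(p.V * p.area, wt, cfg)
        values.append(tc / TC_PER_TG)
    return pd.Series(values, index=traj.years)


def assemble_ledger(
    traj: Trajectory,
    chain: pd.DataFrame,
    savings_tc: pd.Series | None,
    species_table: SpeciesTable | None = None,
    cfg: WoodChainConfig | None = None,
) -> CarbonLedger:
    """Assemble the three-component ledger on the trajectory's time grid.

    ``chain`` is the wood-chain output of
    :func:`sylvasim.wood_chain.run_wood_chain` for this trajectory;
    ``savings_tc`` the per-step substitution credits (tC) versus the
    reference (``None`` for the reference itself, whose substitution
    component is identically zero).
    """
    cfg = cfg or WoodChainConfig()
    years = pd.Index(traj.years, name="year")
    if not chain.index.equals(years):
        raise ValidationError("wood-chain series does not share the trajectory grid")
    in_situ = in_situ_stock(traj, species_table, cfg)
    products = chain["stock_total_tC"] / TC_PER_TG
    if savings_tc is None:
        substitution = pd.Series(0.0, index=years)
    else:
        if not savings_tc.index.equals(years):
            raise ValidationError("savings series does not share the trajectory grid")
        substitution = savings_tc.cumsum() / TC_PER_TG
    frame = pd.DataFrame({
        "in_situ": in_situ,
        "products": products,
        "substitution": substitution,
    })
    frame["total"] = frame.sum(axis=1)
    frame["energy_annual"] = chain["energy_Mtoe"] / 5.0  # Mtoe yr⁻¹ over each step
    frame["energy_cum"] = chain["energy_Mtoe"].cumsum()
    return CarbonLedger(frame)


def carbon_efficiency(ledger: CarbonLedger) -> pd.Series:
    """Cumulative total balance / cumulative energy (Mt C per Mtoe).

    Defined from the first step with positive cumulative energy; earlier
    steps are NaN.  An all-zero energy series yields an empty series with
    a warning.
    """
    energy = ledger.frame["energy_cum"]
    if not (energy > 0).any():
        import warnings

        warnings.warn("no energy produced; efficiency series is empty")
        return pd.Series(dtype=float)
    eff = ledger.frame["total"].where(energy > 0) / energy.where(energy > 0)
    return eff


def run_scenario_ledgers(
    plots: Sequence,
    gp,
    mr: Mapping[str, float],
    th,
    lib,
    scenario_specs: Mapping[str, object],
    horizon: float,
    species_table: SpeciesTable | None = None,
    cfg: WoodChainConfig | None = None,
) -> dict[str, CarbonLedger]:
    """Run several scenarios on the same classified inventory and ledger them.

    ``scenario_specs`` maps label -> :class:`~sylvasim.scenarios.ScenarioSpec`;
    a ``"BaU"`` entry is required and serves as the substitution reference.
    Returns label -> :class:`CarbonLedger`.
    """
    from .growth import run_simulation
    from .wood_chain import run_wood_chain, substitution_savings

    if "BaU" not in scenario_specs:
        raise ValidationError("scenario_specs must contain a 'BaU' reference entry")
    cfg = cfg or WoodChainConfig()
    inflow_cols = {f"inflow_{p}_tC": p for p in ("timber", "paper", "pulp", "energy")}
    runs = {}
    for label, spec in scenario_specs.items():
        traj = run_simulation(plots, gp, mr, th, lib, spec, horizon, species_table)
        flows = traj.harvest
        if not flows.empty:
            flows = flows.groupby(["year", "wood_type", "source"], as_index=False)[
                "volume_m3"
            ].sum()
        runs[label] = (traj, run_wood_chain(flows, traj.years, cfg))
    bau_traj, bau_chain = runs["BaU"]
    bau_inflows = bau_chain[list(inflow_cols)].rename(columns=inflow_cols)
    ledgers = {}
    for label, (traj, chain) in runs.items():
        if label == "BaU":
            savings = None
        else:
            savings = substitution_savings(
                chain[list(inflow_cols)].rename(columns=inflow_cols), bau_inflows,
            )
        ledgers[label] = assemble_ledger(traj, chain, savings, species_table, cfg)
    return ledgers


def parity_time(scenario: CarbonLedger, bau: CarbonLedger) -> float | None:
    """First year the scenario's total balance re-reaches the reference's.

    If the scenario is never behind, parity is the start year (no debt is
    ever opened).  If the balance stays behind through the whole horizon,
    there is no parity (``None``).
    """
    if not scenario.frame.index.equals(bau.frame.index):
        raise ValidationError("ledgers must share the time grid")
    diff = scenario.frame["total"] - bau.frame["total"]
    behind = diff < -1e-12
    if not behind.any():
        return float(scenario.frame.index[0])
    first_behind = np.argmax(behind.to_numpy())
    after = diff.iloc[first_behind:]
    recovered = after >= -1e-12
    if not recovered.any():
        return None
    return float(after.index[np.argmax(recovered.to_numpy())])
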