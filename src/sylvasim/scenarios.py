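"""Management scenarios: business-as-usual and intensification families.

Five families, each resolved into per-approach rules:

* **BaU** — reference: actively-managed plots are thinned and clearcut at
  the current-practice diameter; overstocked plots are clearcut at
  diameter but never thinned; harvest-delayed and unexploitable plots are
  untouched.
* **O_v** (intensity 1-10) — thin 10·intensity % of the overstocked area
  at the current thinning ratio (everything else as BaU).
* **D** (intensity 1-10) — harvest 10·intensity % of the harvest-delayed
  area (everything else as BaU).
* **M** (intensity 1-10) — lower the clearcut diameter of all
  actively-managed plots by ``intensity`` cm.
* **A** (intensity 1-10) — the union of O_v, D, M at the same index (the
  three families touch disjoint approaches, so no conflicts arise).

Extra mobilization ramps up linearly over 30 years from zero to the
target area share; the mobilized plots are those with the largest
diameters (harvest-delayed) or the highest density (overstocked),
selected area-weighted with a deterministic plot-id tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .inventory_io import PlotState, ValidationError

__all__ = [
    "ScenarioSpec",
    "build_scenario",
    "mobilization_schedule",
    "select_plots",
    "energy_target",
    "FAMILIES",
]

FAMILIES = ("BaU", "O_v", "D", "M", "A")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully resolved intensification scenario."""

    family: str
    intensity: int = 0  # 1-10 for intensification families, 0 for BaU
    ramp_years: float = 30.0
    start_year: int = 2015
    delayed_use_buffer: bool = False  # optional FIFO store of energy biomass
    buffer_horizon: float = 10.0  # yr the buffer may hold biomass

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown scenario family {self.family!r}")
        if self.family == "BaU":
            if self.intensity != 0:
                raise ValidationError("BaU takes no intensity")
        elif not 1 <= self.intensity <= 10:
            raise ValidationError("intensity must be in 1..10")

    # --- resolved per-approach rules -------------------------------------
    @property
    def thins_overstocked(self) -> bool:
        return self.family in ("O_v", "A")

    @property
    def harvests_delayed(self) -> bool:
        return self.family in ("D", "A")

    @property
    def diameter_reduction_cm(self) -> float:
        """Clearcut-diameter reduction for actively-managed plots (M, A)."""
        return float(self.intensity) if self.family in ("M", "A") else 0.0

    @property
    def target_fraction(self) -> float:
        """Targeted share of the eligible area for mobilization (O_v, D, A)."""
        return self.intensity * 0.10 if self.family in ("O_v", "D", "A") else 0.0

    @property
    def label(self) -> str:
        return "BaU" if self.family == "BaU" else f"{self.family}-{self.intensity}"


def build_scenario(
    family: str,
    intensity: int = 0,
    start_year: int = 2015,
    ramp_years: float = 30.0,
    delayed_use_buffer: bool = False,
) -> ScenarioSpec:
    """Resolve a scenario from its family and intensity index."""
    family = {"Ov": "O_v"}.get(family, family)
    return ScenarioSpec(family, intensity, ramp_years, start_year, delayed_use_buffer)


def mobilization_schedule(
    target_fraction: float, years_since_start: float, ramp_years: float = 30.0
) -> float:
    """Active mobilized fraction: linear 0 → target over the ramp, then flat."""
    if not 0 <= target_fraction <= 1:
        raise ValidationError("target fraction must be in [0, 1]")
    if years_since_start <= 0:
        return 0.0
    return target_fraction * min(years_since_start / ramp_years, 1.0)


def select_plots(
    plots: Sequence[PlotState], family: str, active_fraction: float
) -> list[PlotState]:
    """Plots to mobilize for one intensification family at the given fraction.

    D ranks harvest-delayed plots by descending Dg; O_v ranks overstocked
    plots by descending DI.  Plots are taken in rank order until the
    accumulated area reaches ``active_fraction`` of the eligible area
    (so the selected share overshoots by at most one plot); ties break by
    plot id for determinism.
    """
    family = {"Ov": "O_v"}.get(family, family)
    if family == "D":
        eligible = [p for p in plots if p.mgmt == "harvest-delayed"]
        key = lambda p: (-p.Dg, p.plot_id)
    elif family == "O_v":
        eligible = [p for p in plots if p.mgmt == "overstocked"]
        key = lambda p: (-p.DI, p.plot_id)
    else:
        raise ValidationError(f"family {family!r} does not mobilize plots")
    if active_fraction <= 0 or not eligible:
        return []
    target_area = active_fraction * sum(p.area for p in eligible)
    selected: list[PlotState] = []
    acc = 0.0
    for p in sorted(eligible, key=key):
        if acc >= target_area - 1e-12:
            break
        selected.append(p)
        acc += p.area
    return selected


def energy_target(year: float, variant: str = "basic") -> float:
    """National wood-energy production target (Mtoe yr⁻¹).

    Both variants start from 9.7 Mtoe in 2015.  ``basic`` ramps linearly
    to 11.6 Mtoe in 2026 (an increase of 1.9 Mtoe) and is then held
    constant; ``ambitious`` grows by 0.25 Mtoe per year until 2040 and is
    held constant after.
    """
    if year < 2015:
        raise ValidationError("energy target defined from 2015 onward")
    if variant == "basic":
        if year >= 2026:
            return 11.6
        return 9.7 + 1.9 * (year - 2015) / (2026 - 2015)
    if variant == "ambitious":
        return 9.7 + 0.25 * (min(year, 2040) - 2015)
    raise ValidationError(f"unknown target variant {variant!r}")
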