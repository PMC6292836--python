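"""Management-approach classification and threshold calibration.

Every plot is assigned exactly one of four management approaches by a
fixed priority order:

1. **unexploitable** — exploitability below the workable floor
   (physically constrained terrain);
2. **harvest-delayed** — quadratic mean diameter above the
   current-practice clearcut diameter for its species × fertility class
   (over-mature, left unharvested for ownership reasons);
3. **overstocked** — relative density index above the species threshold
   (unthinned but eventually clearcut);
4. **actively-managed** — everything else (thinned and clearcut).

Threshold priors come from discontinuities in the empirical diameter and
density distributions, located by a two-segment piecewise-constant fit to
a fixed-width histogram with the breakpoint chosen by an SSE scan: under
even-aged idealized management all diameter classes below the harvest
diameter are similarly populated while none lie above it, so the harvest
diameter appears as a step in the frequency.  Thresholds are then
calibrated so the simulated first-step harvest matches reported
per-species harvest: first the exploitability floor, then the thinning
ratio by bisection (the clearcut-diameter priors are never calibrated).

Species exceptions (plots managed regardless of exploitability or
stocking, as observed for intensively marketed species) are applied
before the priority rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .inventory_io import EXPLOIT_LEVELS, MGMT_APPROACHES, PlotState, ValidationError

__all__ = [
    "ManagementThresholds",
    "SpeciesThresholds",
    "BreakpointResult",
    "detect_diameter_threshold",
    "detect_density_threshold",
    "classify_plot",
    "classify",
    "calibrate",
    "CalibrationResult",
    "NATIONAL_CALIBRATED_THINNING",
]

# Real-data calibration outcome shipped as a named configuration (yearly
# thinning ratios after calibration against reported national harvest).
NATIONAL_CALIBRATED_THINNING: dict[str, float] = {
    "Quercus petraea": 0.08,
    "Picea abies": 0.11,
    "Pinus pinaster": 0.13,
}
# Species managed without a stocking-density or exploitability threshold.
DEFAULT_EXEMPT_SPECIES: tuple[str, ...] = ("Pinus pinaster", "Picea abies")


@dataclass
class SpeciesThresholds:
    """Thresholds for one species.

    ``clearcut_diameter`` maps fertility class -> Dg threshold (cm); an
    empty-string key is the class-independent fallback.  ``thinning_ratio``
    is the yearly fraction of standing volume removed by thinning.
    """

    clearcut_diameter: dict[str, float]
    di_threshold: float = np.inf
    thinning_ratio: float = 0.05
    exempt: bool = False  # no DI / exploitability threshold applies

    def __post_init__(self) -> None:
        for v in self.clearcut_diameter.values():
            if not v > 7.5:
                raise ValidationError("clearcut diameter must exceed 7.5 cm")
        if not 0 <= self.thinning_ratio < 1:
            raise ValidationError("thinning ratio must be in [0, 1)")
        if not self.di_threshold > 0:
            raise ValidationError("DI threshold must be > 0")

    def clearcut_dg(self, fert_class: str) -> float:
        if fert_class in self.clearcut_diameter:
            return self.clearcut_diameter[fert_class]
        if "" in self.clearcut_diameter:
            return self.clearcut_diameter[""]
        raise ValidationError(f"no clearcut diameter for fertility class {fert_class!r}")


@dataclass
class ManagementThresholds:
    """Per-species thresholds plus the global exploitability floor.

    ``exploitability_floor`` is the worst level still workable
    (default ``"difficult"``: only ``impossible`` plots are unexploitable).
    """

    species: dict[str, SpeciesThresholds]
    exploitability_floor: str = "difficult"

    def __post_init__(self) -> None:
        if self.exploitability_floor not in EXPLOIT_LEVELS:
            raise ValidationError(f"bad exploitability floor {self.exploitability_floor!r}")

    def for_species(self, name: str) -> SpeciesThresholds:
        try:
            return self.species[name]
        except KeyError:
            raise ValidationError(f"no thresholds configured for species {name!r}") from None

    def copy(self) -> "ManagementThresholds":
        return ManagementThresholds(
            {k: replace(v, clearcut_diameter=dict(v.clearcut_diameter))
             for k, v in self.species.items()},
            self.exploitability_floor,
        )


@dataclass(frozen=True)
class BreakpointResult:
    """Outcome of the two-segment histogram scan."""

    threshold: float
    fallback: bool  # True when no significant discontinuity was found
    sse: float = np.nan


def _segmented_breakpoint(
    values: Sequence[float],
    bin_width: float,
    min_n: int,
    fallback_quantile: float,
    z: float,
) -> BreakpointResult:
    """Two-segment piecewise-constant fit to a fixed-width histogram.

    Scans every interior bin edge as candidate breakpoint, fitting a
    constant to the left and right bin counts; keeps the SSE-minimal
    edge.  The break is significant only if the downward step between
    the segment means exceeds ``z`` × the pooled within-segment SD of
    the bin counts — a genuine cliff, not the smooth tail of a unimodal
    distribution.  Otherwise the ``fallback_quantile`` of the data is
    returned with a warning.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < min_n:
        raise ValidationError(f"need at least {min_n} values, got {len(x)}")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    best = None
    for i in range(1, len(counts)):
        left, right = counts[:i], counts[i:]
        sse = float(((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, i, left.mean(), right.mean())
    sse, i, left_mean, right_mean = best
    pooled_sd = np.sqrt(sse / max(len(counts) - 2, 1))
    if left_mean - right_mean >= z * pooled_sd and left_mean > 0:
        return BreakpointResult(float(edges[i]), fallback=False, sse=sse)
    warnings.warn(
        "no significant discontinuity in the distribution; "
        f"falling back to the {fallback_quantile:.0%} quantile"
    )
    return BreakpointResult(float(np.quantile(x, fallback_quantile)), fallback=True, sse=sse)


def detect_diameter_threshold(
    dg_values: Sequence[float],
    bin_width: float = 2.0,
    min_n: int = 50,
    fallback_quantile: float = 0.95,
    z: float = 2.0,
) -> BreakpointResult:
    """Clearcut-diameter prior (cm) for one species × fertility class.

    Under idealized even-aged management every diameter class below the
    harvest diameter is similarly populated and none lies above it, so
    the harvest diameter shows up as a step to near-zero density.
    """
    return _segmented_breakpoint(dg_values, bin_width, min_n, fallback_quantile, z)


def detect_density_threshold(
    di_values: Sequence[float],
    bin_width: float = 0.05,
    min_n: int = 50,
    fallback_quantile: float = 0.95,
    z: float = 2.0,
) -> BreakpointResult:
    """Density-index threshold prior for one species.

    Unlike the diameter case the over-threshold (overstocked) mass is
    real rather than empty; the break is the step between the dense
    managed body and the sparser overstocked tail.
    """
    return _segmented_breakpoint(di_values, bin_width, min_n, fallback_quantile, z)


def _exploit_rank(level: str) -> int:
    return EXPLOIT_LEVELS.index(level)


def classify_plot(plot: PlotState, th: ManagementThresholds) -> str:
    """Assign one management approach by the fixed priority order.

    Priority 1: exploitability worse than the floor -> unexploitable
    (exempt species skip this rule).  Priority 2: Dg above the clearcut
    diameter -> harvest-delayed.  Priority 3: DI above the species
    threshold -> overstocked (exempt species skip this rule too).
    Priority 4: actively-managed.
    """
    sp = th.for_species(plot.main_species)
    if not sp.exempt:
        if plot.exploit and _exploit_rank(plot.exploit) > _exploit_rank(th.exploitability_floor):
            return "unexploitable"
    if plot.Dg == plot.Dg and plot.Dg > sp.clearcut_dg(plot.fert_class):
        return "harvest-delayed"
    if not sp.exempt:
        if plot.DI == plot.DI and plot.DI > sp.di_threshold:
            return "overstocked"
    return "actively-managed"


def classify(plots: Iterable[PlotState], th: ManagementThresholds) -> list[PlotState]:
    """Classify every plot, returning copies with ``mgmt`` filled in."""
    return [p.copy(mgmt=classify_plot(p, th)) for p in plots]


@dataclass
class CalibrationResult:
    thresholds: ManagementThresholds
    converged: bool
    residuals: dict[str, float]  # relative harvest mismatch per species
    trace: list[str] = field(default_factory=list)


def calibrate(
    plots: Sequence[PlotState],
    priors: ManagementThresholds,
    reported_harvest: Mapping[str, float],
    harvest_evaluator: Callable[[Sequence[PlotState], ManagementThresholds], Mapping[str, float]],
    rel_tol: float = 0.05,
    thinning_bounds: tuple[float, float] = (0.0, 0.3),
    max_iter: int = 60,
) -> CalibrationResult:
    """Calibrate thresholds so the first-step harvest matches reports.

    ``harvest_evaluator(plots, thresholds)`` must return the simulated
    first-step yearly harvest per species (m³ yr⁻¹) under the candidate
    thresholds.  Calibration is deterministic coordinate descent: the
    exploitability floor is chosen first over its ordinal values (it has
    the strongest direct effect — unworkable stands are simply not
    managed), then each species' thinning ratio is bisected within
    ``thinning_bounds`` until the relative mismatch is below ``rel_tol``.
    Clearcut-diameter priors are never touched.
    """
    trace: list[str] = []

    def total_misfit(th: ManagementThresholds) -> float:
        sim = harvest_evaluator(plots, th)
        return sum(
            abs(sim.get(s, 0.0) - r) / r for s, r in reported_harvest.items() if r > 0
        )

    # 1. exploitability floor over its ordinal values
    best_floor, best_misfit = None, np.inf
    for floor in EXPLOIT_LEVELS:
        th = priors.copy()
        th.exploitability_floor = floor
        m = total_misfit(th)
        trace.append(f"floor={floor}: total relative misfit {m:.4f}")
        if m < best_misfit:
            best_floor, best_misfit = floor, m
    th = priors.copy()
    th.exploitability_floor = best_floor
    trace.append(f"selected exploitability floor: {best_floor}")

    # 2. per-species thinning ratio by bisection (harvest is monotone
    # non-decreasing in the thinning ratio)
    residuals: dict[str, float] = {}
    for species, reported in sorted(reported_harvest.items()):
        if reported <= 0 or species not in th.species:
            continue
        lo, hi = thinning_bounds

        def harvest_at(ratio: float) -> float:
            th.species[species].thinning_ratio = ratio
            return harvest_evaluator(plots, th)[species]

        h_lo, h_hi = harvest_at(lo), harvest_at(hi)
        if reported <= h_lo:
            ratio, sim = lo, h_lo
        elif reported >= h_hi:
            ratio, sim = hi, h_hi
        else:
            for _ in range(max_iter):
                mid = 0.5 * (lo + hi)
                h_mid = harvest_at(mid)
                if abs(h_mid - reported) / reported <= rel_tol:
                    break
                if h_mid < reported:
                    lo = mid
                else:
                    hi = mid
            ratio, sim = mid, h_mid
        th.species[species].thinning_ratio = ratio
        residuals[species] = abs(sim - reported) / reported
        trace.append(
            f"{species}: thinning ratio {ratio:.4f}, relative residual {residuals[species]:.4f}"
        )
    converged = all(r <= rel_tol for r in residuals.values())
    return CalibrationResult(th, converged, residuals, trace)
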