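"""Per-plot indices and stand-level increments derived from tree records.

Three empirical relationships anchor the stand description:

* a Hossfeld II guide curve ``h0(age) = a / (1 + (b/age)^c)`` per species,
  used to transfer an observed dominant height to the site index H100
  (dominant height at the 100-yr reference age) by proportional scaling;
* a self-thinning frontier ``log N_max = g + h log Dg`` bounding stem
  number from above at a given quadratic mean diameter, whose ratio
  ``DI = N / N_max`` is the relative density index;
* a per-species allometry ``v = f(r)`` between stem volume and above-bark
  radius (power law by default), used to reconstruct 5-year tree volume
  increments from the recorded radius increment and bark ratio.

Stand-level increments aggregate trees by their statistical weights: the
volume increment sums over all species in the plot, the radius increment
averages over the main species only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull

from .inventory_io import EXPLOIT_LEVELS, TreeRecord, ValidationError

__all__ = [
    "GuideCurve",
    "SelfThinning",
    "VolumeRadiusFit",
    "BarkRatio",
    "ExploitabilityRules",
    "FitError",
    "fit_guide_curve",
    "site_index",
    "assign_fertility_classes",
    "fit_self_thinning",
    "density_index",
    "load_exploitability_rules",
    "exploitability",
    "fit_volume_radius",
    "previous_radius",
    "tree_volume_increment",
    "stand_increments",
    "quadratic_mean_diameter",
    "replicate_avg_tree",
]


class FitError(RuntimeError):
    """A statistical fit failed; carries diagnostics where available."""


# ---------------------------------------------------------------------------
# Guide curve and site index


@dataclass(frozen=True)
class GuideCurve:
    """Hossfeld II dominant height-age curve ``h0 = a / (1 + (b/age)^c)``.

    ``a`` is the asymptotic dominant height (m), ``b`` the age at which
    half the asymptote is reached (yr), ``c`` a unitless shape exponent.
    """

    species: str
    a: float
    b: float
    c: float
    resid_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValidationError("guide curve parameters must be positive")

    def h0(self, age):
        age = np.asarray(age, dtype=float)
        return self.a / (1.0 + (self.b / age) ** self.c)

    @property
    def H100(self) -> float:
        return float(self.h0(100.0))


def _hossfeld(age, a, b, c):
    return a / (1.0 + (b / age) ** c)


def fit_guide_curve(
    ages: Sequence[float],
    heights: Sequence[float],
    species: str = "",
    p0: tuple[float, float, float] = (30.0, 40.0, 1.2),
) -> GuideCurve:
    """Least-squares fit of the guide curve to (age, dominant height) pairs."""
    ages = np.asarray(ages, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if len(ages) < 10:
        raise FitError("need at least 10 (age, h0) pairs")
    if np.ptp(ages) <= 0:
        raise FitError("age range is degenerate")
    try:
        popt, _ = curve_fit(
            _hossfeld, ages, heights, p0=p0,
            bounds=([1e-6, 1e-6, 1e-6], [200.0, 500.0, 10.0]), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"guide curve fit did not converge: {exc}") from exc
    resid = heights - _hossfeld(ages, *popt)
    sd = float(np.sqrt(np.mean(resid**2)))
    return GuideCurve(species, float(popt[0]), float(popt[1]), float(popt[2]), sd)


def site_index(h0_plot: float, age: float, guide: GuideCurve,
               age_support: tuple[float, float] | None = None) -> float:
    """Site index H100 of a plot by proportional transfer along the guide.

    Assuming the curve shape (b, c) is shared across fertility levels,
    ``H100_plot / h0_plot(age) = H100_guide / h0_guide(age)``, so
    ``H100 = h0_plot * H100_guide / h0_guide(age)``.
    """
    if not age > 0:
        raise ValidationError("age must be > 0")
    if not h0_plot > 0:
        raise ValidationError("h0 must be > 0")
    if age_support is not None and not (age_support[0] <= age <= age_support[1]):
        warnings.warn(f"age {age} outside fitted support {age_support}; extrapolating")
    return h0_plot * guide.H100 / float(guide.h0(age))


def assign_fertility_classes(
    h100: Sequence[float], n_classes: int = 3
) -> tuple[np.ndarray, list[str]]:
    """Cut site indices into equal-probability quantile classes.

    Boundaries are linear-interpolation quantiles of the values.  Returns
    ``(labels, boundaries_repr)`` where labels[i] is ``"F1"`` (lowest
    fertility) .. ``"F<k>"``.  Ties that collapse a class merge it with a
    warning; all-equal values yield a single class.
    """
    x = np.asarray(h100, dtype=float)
    if len(np.unique(x)) < n_classes:
        warnings.warn("fewer distinct values than classes; classes merged")
    qs = np.quantile(x, np.linspace(0, 1, n_classes + 1)[1:-1])
    bounds = np.unique(qs)
    labels = np.array([f"F{i + 1}" for i in np.searchsorted(bounds, x, side="left")])
    return labels, [f"F{i + 1}" for i in range(len(bounds) + 1)]


# ---------------------------------------------------------------------------
# Self-thinning frontier and density index


@dataclass(frozen=True)
class SelfThinning:
    """Log-log self-thinning frontier ``log N_max = g + h log Dg`` (h < 0)."""

    species: str
    g: float
    h: float

    def n_max(self, dg):
        return np.exp(self.g) * np.asarray(dg, dtype=float) ** self.h


def fit_self_thinning(
    dg: Sequence[float],
    n: Sequence[float],
    age: Sequence[float] | None = None,
    species: str = "",
    method: str = "quantile",
    tau: float = 0.99,
    age_percentiles: tuple[float, float] = (10.0, 90.0),
    min_plots: int = 30,
) -> SelfThinning:
    """Fit the upper log-log envelope of stem number versus mean diameter.

    Plots with age outside the ``age_percentiles`` (default 10th-90th) are
    excluded first.  ``method="quantile"`` (default) fits a quantile
    regression at ``tau`` on the log-log scale and then refits OLS on the
    points at or above that line; ``method="hull"`` takes the upper chain
    of the convex hull of the log-log cloud and fits OLS through its
    vertices.
    """
    dg = np.asarray(dg, dtype=float)
    n = np.asarray(n, dtype=float)
    keep = np.ones(len(dg), dtype=bool)
    if age is not None:
        age = np.asarray(age, dtype=float)
        lo, hi = np.percentile(age, age_percentiles)
        keep = (age >= lo) & (age <= hi)
    x, y = np.log(dg[keep]), np.log(n[keep])
    if len(x) < min_plots:
        raise FitError(
            f"only {len(x)} plots after age filter (< {min_plots}); consider pooling"
        )
    if method == "quantile":
        import statsmodels.api as sm

        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qr = sm.QuantReg(y, X).fit(q=tau)
        upper = y >= (qr.params[0] + qr.params[1] * x) - 1e-9
        if upper.sum() < 2:
            upper = np.argsort(y - qr.predict(X))[-2:]
        h, g = np.polyfit(x[upper], y[upper], 1)
    elif method == "hull":
        pts = np.column_stack([x, y])
        hull = ConvexHull(pts)
        verts = list(hull.vertices)  # counterclockwise polygon
        i_max = max(range(len(verts)), key=lambda i: pts[verts[i], 0])
        i_min = min(range(len(verts)), key=lambda i: pts[verts[i], 0])
        # walking CCW from the max-x vertex to the min-x vertex traverses
        # the upper chain of the hull
        chain = []
        i = i_max
        while True:
            chain.append(verts[i])
            if i == i_min:
                break
            i = (i + 1) % len(verts)
        # the frontier is the dominant facet of the upper chain: short
        # corner facets near the x-extremes belong to the cloud bulge, so
        # fit the line through the endpoints of the longest-x facet
        spans = [abs(pts[chain[i + 1], 0] - pts[chain[i], 0]) for i in range(len(chain) - 1)]
        j = int(np.argmax(spans))
        (x1, y1), (x2, y2) = pts[chain[j]], pts[chain[j + 1]]
        h = (y2 - y1) / (x2 - x1)
        g = y1 - h * x1
    else:
        raise ValueError(f"unknown method {method!r}")
    return SelfThinning(species, float(g), float(h))


def density_index(n: float, dg: float, st: SelfThinning) -> float:
    """Relative density index ``DI = N / (e^g Dg^h)``."""
    if not (n > 0 and dg > 0):
        raise ValidationError("N and Dg must be > 0")
    return float(n / st.n_max(dg))


# ---------------------------------------------------------------------------
# Exploitability


@dataclass(frozen=True)
class ExploitabilityRules:
    """Ordinal rule table mapping terrain descriptors to an exploitability level.

    ``levels_by_descriptor[d][category] -> level``.  The default rule is
    worst-category-dominates: the plot level is the worst level among its
    descriptors (ordering very-easy < easy < difficult < impossible).
    """

    levels_by_descriptor: Mapping[str, Mapping[str, str]]
    rule: str = "worst-dominates"

    @property
    def descriptors(self) -> list[str]:
        return list(self.levels_by_descriptor)

    def categories(self, descriptor: str) -> list[str]:
        return list(self.levels_by_descriptor[descriptor])


def load_exploitability_rules(path: str | Path | None = None) -> ExploitabilityRules:
    if path is None:
        path = Path(__file__).parent / "data" / "exploitability_rules.yaml"
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    table = {
        name: dict(zip(spec["categories"], spec["levels"]))
        for name, spec in cfg["descriptors"].items()
    }
    return ExploitabilityRules(table, cfg.get("rule", "worst-dominates"))


def exploitability(descriptors: Mapping[str, str], rules: ExploitabilityRules) -> str:
    """Exploitability level of a plot from its four terrain descriptors."""
    missing = set(rules.descriptors) - set(descriptors)
    if missing:
        raise ValidationError(f"missing terrain descriptors: {sorted(missing)}")
    levels = []
    for name in rules.descriptors:
        cat = descriptors[name]
        try:
            levels.append(rules.levels_by_descriptor[name][cat])
        except KeyError:
            raise ValidationError(f"unknown category {cat!r} for {name}") from None
    if rules.rule != "worst-dominates":  # pragma: no cover - only default shipped
        raise ValidationError(f"unknown rule {rules.rule!r}")
    return max(levels, key=EXPLOIT_LEVELS.index)


# ---------------------------------------------------------------------------
# Volume-radius allometry and increment reconstruction


@dataclass(frozen=True)
class VolumeRadiusFit:
    """Power-law stem allometry ``v = k r^m`` fitted on the log-log scale."""

    species: str
    k: float
    m: float
    resid_sd: float = 0.0  # SD of log residuals

    def __call__(self, r):
        return self.k * np.asarray(r, dtype=float) ** self.m


@dataclass(frozen=True)
class BarkRatio:
    """Bark fraction of above-bark radius, 0 <= beta < 1."""

    species: str
    beta: float

    def __post_init__(self) -> None:
        if not 0 <= self.beta < 1:
            raise ValidationError("bark ratio must be in [0, 1)")


def fit_volume_radius(trees: Iterable[TreeRecord], species: str = "",
                      min_trees: int = 20) -> VolumeRadiusFit:
    """Fit ``v = k r^m`` to alive trees of a species by log-log least squares."""
    pts = [(t.r_ab, t.v_ab) for t in trees if t.status == "alive" and t.v_ab > 0]
    if len(pts) < min_trees:
        raise FitError(f"only {len(pts)} usable trees (< {min_trees})")
    r, v = map(np.asarray, zip(*pts))
    if np.ptp(r) <= 0:
        raise FitError("degenerate radius range")
    m, logk = np.polyfit(np.log(r), np.log(v), 1)
    resid = np.log(v) - (logk + m * np.log(r))
    return VolumeRadiusFit(species, float(np.exp(logk)), float(m),
                           float(np.std(resid)))


def previous_radius(r_ab: float, ir_bb: float, beta: float) -> float:
    """Above-bark radius 5 years ago from the below-bark increment.

    ``r(t-5) = ((1 - beta) r(t) - ir(t)) / (1 - beta)``; a non-positive
    result marks the record inconsistent.
    """
    prev = ((1.0 - beta) * r_ab - ir_bb) / (1.0 - beta)
    if not prev > 0:
        raise ValidationError(
            f"non-positive previous radius ({prev:.4f} m) for r={r_ab}, ir={ir_bb}"
        )
    return prev


def tree_volume_increment(tree: TreeRecord, fit: VolumeRadiusFit, beta: float) -> float:
    """5-year tree volume increment ``iv = v (1 - f(r_{t-5}) / f(r_t))``."""
    r_prev = previous_radius(tree.r_ab, tree.ir_bb, beta)
    return tree.v_ab * (1.0 - float(fit(r_prev)) / float(fit(tree.r_ab)))


def stand_increments(
    trees: Iterable[TreeRecord],
    main_species: str,
    fits: Mapping[str, VolumeRadiusFit],
    betas: Mapping[str, float],
    skip_inconsistent: bool = True,
) -> tuple[float, float, int]:
    """Stand-level 5-yr volume and radius increments from tree records.

    ``IV`` is the weighted sum of per-tree volume increments over all
    alive trees of every species; ``Ir`` is the weighted mean below-bark
    radius increment over alive main-species trees only.  Dead trees are
    excluded (mortality is handled separately).  Returns
    ``(IV m³/5yr, Ir m/5yr, n_inconsistent)``; trees whose reconstructed
    previous radius is non-positive are skipped and counted.
    """
    iv_sum = 0.0
    ir_num = ir_den = 0.0
    n_main = 0
    n_bad = 0
    for t in trees:
        if t.status != "alive":
            continue
        try:
            iv_sum += tree_volume_increment(t, fits[t.species], betas[t.species]) * t.w
        except ValidationError:
            if not skip_inconsistent:
                raise
            n_bad += 1
            continue
        if t.species == main_species:
            ir_num += t.ir_bb * t.w
            ir_den += t.w
            n_main += 1
    if n_main == 0:
        raise ValidationError(f"no alive tree of main species {main_species!r}; Ir undefined")
    return iv_sum, ir_num / ir_den, n_bad


def quadratic_mean_diameter(trees: Iterable[TreeRecord], main_species: str) -> float:
    """Quadratic mean diameter (cm) of the main species,
    ``Dg = 100 sqrt(4/pi * G / N)`` with basal area from above-bark radii."""
    g_sum = w_sum = 0.0
    for t in trees:
        if t.status == "alive" and t.species == main_species:
            g_sum += np.pi * t.r_ab**2 * t.w
            w_sum += t.w
    if w_sum == 0:
        raise ValidationError(f"no alive tree of main species {main_species!r}")
    return 100.0 * float(np.sqrt(4.0 / np.pi * g_sum / w_sum))


def replicate_avg_tree(
    v_stand: float, trees: Iterable[TreeRecord], main_species: str
) -> tuple[float, float]:
    """Idealized average tree and reconstructed stem count.

    ``v_avgtree`` is the weighted mean volume over alive main-species
    trees; ``N = V_stand / v_avgtree`` replicates it so the idealized
    stand carries exactly the reported per-ha volume.
    """
    v_num = w_sum = 0.0
    for t in trees:
        if t.status == "alive" and t.species == main_species:
            v_num += t.v_ab * t.w
            w_sum += t.w
    if w_sum == 0 or v_num == 0:
        raise ValidationError("main-species weighted volume is zero; N undefined")
    v_avg = v_num / w_sum
    return v_avg, v_stand / v_avg
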