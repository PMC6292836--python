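"""Data model and delimited-text I/O for plot, tree, and species tables.

Tables are comma-separated UTF-8 with a mandatory header row.  Units are
fixed at the interface: tree radii in metres (above bark), radius
increments in metres per 5 years (below bark), volumes in m³, plot volume
in m³ ha⁻¹, quadratic mean diameter in cm, areas in km² (species table)
or ha (plot ``area`` column).

National upscaling uses equal weights for all plots within each
species × region cell; the cell mean of each per-hectare variable is then
multiplied by the reported area of the cell.  Per-plot statistical
weights of the source inventory are not public, so this equal-weight
convention is the implemented one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TreeRecord",
    "PlotState",
    "SpeciesTable",
    "FormatError",
    "ValidationError",
    "ConsistencyError",
    "UnmappedSpeciesError",
    "read_tree_table",
    "write_tree_table",
    "read_plot_table",
    "write_plot_table",
    "read_species_table",
    "write_species_table",
    "default_species_table",
    "upscale",
]


class FormatError(ValueError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """A row violates a field invariant (e.g. negative radius)."""


class ConsistencyError(ValueError):
    """Subtotal/total rows disagree with the sum of member rows."""


class UnmappedSpeciesError(KeyError):
    """A species present in the plots is absent from the species table."""


EXPLOIT_LEVELS = ("very-easy", "easy", "difficult", "impossible")
MGMT_APPROACHES = ("unexploitable", "harvest-delayed", "overstocked", "actively-managed")


@dataclass(frozen=True)
class TreeRecord:
    """One inventoried tree.

    Attributes
    ----------
    tree_id : str
        Identifier, unique within its plot.
    species : str
        Species code.
    r_ab : float
        Above-bark radius at breast height (m); > 0 for alive trees.
    ir_bb : float
        Below-bark radius increment over the last 5 years (m / 5 yr), >= 0.
    v_ab : float
        Above-bark stem volume (m³), >= 0.
    w : float
        Statistical weight of the tree within its plot (per-ha expansion
        factor), > 0.
    status : str
        ``"alive"`` or ``"dead"``.
    """

    tree_id: str
    species: str
    r_ab: float
    ir_bb: float
    v_ab: float
    w: float
    status: str = "alive"

    def __post_init__(self) -> None:
        if self.status not in ("alive", "dead"):
            raise ValidationError(f"tree {self.tree_id}: bad status {self.status!r}")
        if self.status == "alive" and not self.r_ab > 0:
            raise ValidationError(f"tree {self.tree_id}: alive tree needs r_ab > 0")
        if self.r_ab < 0:
            raise ValidationError(f"tree {self.tree_id}: negative radius")
        if self.ir_bb < 0:
            raise ValidationError(f"tree {self.tree_id}: negative increment")
        if self.v_ab < 0:
            raise ValidationError(f"tree {self.tree_id}: negative volume")
        if not self.w > 0:
            raise ValidationError(f"tree {self.tree_id}: weight must be > 0")


@dataclass
class PlotState:
    """One stand (inventory plot) and its derived indices.

    ``V`` is standing volume (m³ ha⁻¹); ``Dg`` the quadratic mean diameter
    of the main species (cm); ``N`` the reconstructed stem count (ha⁻¹);
    ``DI`` the relative density index; ``H100`` the site index (dominant
    height at 100 yr, m); ``area`` the surface the plot represents (ha).
    """

    plot_id: str
    region: str
    main_species: str
    structure: str = "high-stand"  # or "coppice"
    age: float = float("nan")
    h0: float = float("nan")
    V: float = float("nan")
    Dg: float = float("nan")
    N: float = float("nan")
    DI: float = float("nan")
    H100: float = float("nan")
    fert_class: str = ""
    exploit: str = ""
    mgmt: str = ""
    area: float = 1.0

    def __post_init__(self) -> None:
        if self.structure not in ("high-stand", "coppice"):
            raise ValidationError(f"plot {self.plot_id}: bad structure {self.structure!r}")
        if self.V == self.V and self.V < 0:  # NaN-safe
            raise ValidationError(f"plot {self.plot_id}: negative volume")
        if self.age == self.age and not self.age > 0:
            raise ValidationError(f"plot {self.plot_id}: age must be > 0")
        if not self.area > 0:
            raise ValidationError(f"plot {self.plot_id}: area must be > 0")
        if self.exploit and self.exploit not in EXPLOIT_LEVELS:
            raise ValidationError(f"plot {self.plot_id}: bad exploitability {self.exploit!r}")
        if self.mgmt and self.mgmt not in MGMT_APPROACHES:
            raise ValidationError(f"plot {self.plot_id}: bad management {self.mgmt!r}")

    def copy(self, **changes) -> "PlotState":
        return replace(self, **changes)


@dataclass
class SpeciesTable:
    """Per-species areas (km²), standing volumes (Mm³), and wood type.

    ``frame`` has one row per member species, indexed by species name,
    with columns ``area_km2``, ``volume_Mm3``, ``wood_type``
    ("hardwood"/"softwood").  Volumes may be NaN (not reported).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"area_km2", "volume_Mm3", "wood_type"} - set(self.frame.columns)
        if missing:
            raise FormatError(f"species table missing columns: {sorted(missing)}")
        bad = set(self.frame["wood_type"]) - {"hardwood", "softwood"}
        if bad:
            raise ValidationError(f"unknown wood types: {sorted(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    def wood_type(self, species: str) -> str:
        try:
            return str(self.frame.loc[species, "wood_type"])
        except KeyError:
            raise UnmappedSpeciesError(species) from None

    def area_km2(self, species: str) -> float:
        try:
            return float(self.frame.loc[species, "area_km2"])
        except KeyError:
            raise UnmappedSpeciesError(species) from None

    def total_area_km2(self) -> float:
        return float(self.frame["area_km2"].sum())

    def total_volume_Mm3(self) -> float:
        return float(self.frame["volume_Mm3"].sum(skipna=True))

    def subtotal(self, wood_type: str) -> tuple[float, float]:
        sub = self.frame[self.frame["wood_type"] == wood_type]
        return float(sub["area_km2"].sum()), float(sub["volume_Mm3"].sum(skipna=True))


_TREE_COLUMNS = ["plot_id", "tree_id", "species", "r_ab", "ir_bb", "v_ab", "w", "status"]
_TREE_NUMERIC = ["r_ab", "ir_bb", "v_ab", "w"]


def read_tree_table(path: str | Path) -> dict[str, list[TreeRecord]]:
    """Read a tree table, returning records grouped by plot id.

    Rows with missing mandatory fields are rejected with their (0-based
    data) row index reported.  A header-only file yields an empty dict.
    """
    df = pd.read_csv(path, dtype={"plot_id": str, "tree_id": str, "species": str},
                     float_precision="round_trip")
    missing = set(_TREE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"tree table missing columns: {sorted(missing)}")
    bad_rows = df.index[df[_TREE_COLUMNS].isna().any(axis=1)].tolist()
    if bad_rows:
        raise ValidationError(f"tree table rows with missing fields: {bad_rows}")
    grouped: dict[str, list[TreeRecord]] = {}
    for row in df.itertuples(index=False):
        rec = TreeRecord(
            tree_id=row.tree_id,
            species=row.species,
            r_ab=float(row.r_ab),
            ir_bb=float(row.ir_bb),
            v_ab=float(row.v_ab),
            w=float(row.w),
            status=row.status,
        )
        grouped.setdefault(row.plot_id, []).append(rec)
    return grouped


def write_tree_table(trees: Mapping[str, Iterable[TreeRecord]], path: str | Path) -> None:
    rows = [
        {"plot_id": pid, **{f.name: getattr(t, f.name) for f in fields(TreeRecord)}}
        for pid, recs in trees.items()
        for t in recs
    ]
    pd.DataFrame(rows, columns=_TREE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


_PLOT_STR = ["plot_id", "region", "main_species", "structure", "fert_class", "exploit", "mgmt"]


def read_plot_table(path: str | Path) -> list[PlotState]:
    df = pd.read_csv(path, dtype={c: str for c in _PLOT_STR}, float_precision="round_trip")
    required = {"plot_id", "region", "main_species", "area"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"plot table missing columns: {sorted(missing)}")
    plots = []
    for row in df.to_dict("records"):
        kwargs = {}
        for f in fields(PlotState):
            if f.name in row and row[f.name] == row[f.name]:  # skip NaN
                kwargs[f.name] = row[f.name]
            elif f.name in _PLOT_STR and f.name in row:
                kwargs[f.name] = ""  # NaN string column -> empty
        plots.append(PlotState(**kwargs))
    return plots


def write_plot_table(plots: Iterable[PlotState], path: str | Path) -> None:
    cols = [f.name for f in fields(PlotState)]
    pd.DataFrame([{c: getattr(p, c) for c in cols} for p in plots], columns=cols).to_csv(
        path, index=False, float_format="%.17g"
    )


def plots_to_frame(plots: Iterable[PlotState]) -> pd.DataFrame:
    cols = [f.name for f in fields(PlotState)]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in plots], columns=cols)


def read_species_table(path: str | Path, rtol_last_digit: float = 1.0) -> SpeciesTable:
    """Read a species table and validate subtotal/total rows against sums.

    The file has columns ``species, area_km2, volume_Mm3, wood_type``.
    Rows whose species name starts with ``"Total"`` are check rows: either
    wood-type subtotals (``Total hardwood`` / ``Total softwood``) or the
    grand total (``Total``).  Check rows must agree with the member-row
    sums to within ``rtol_last_digit`` units in the last printed digit
    (default ±1); volumes reported as missing contribute 0.
    """
    df = pd.read_csv(path)
    missing = {"species", "area_km2", "volume_Mm3", "wood_type"} - set(df.columns)
    if missing:
        raise FormatError(f"species table missing columns: {sorted(missing)}")
    is_total = df["species"].str.startswith("Total")
    members = df[~is_total].set_index("species")
    table = SpeciesTable(members[["area_km2", "volume_Mm3", "wood_type"]])
    for row in df[is_total].itertuples(index=False):
        if row.species == "Total":
            got = (table.total_area_km2(), table.total_volume_Mm3())
        else:
            wt = row.species.removeprefix("Total").strip()
            got = table.subtotal(wt)
        for printed, summed, what in [(row.area_km2, got[0], "area"), (row.volume_Mm3, got[1], "volume")]:
            if printed == printed and abs(printed - summed) > rtol_last_digit:
                raise ConsistencyError(
                    f"{row.species} {what}: printed {printed} vs summed {summed}"
                )
    return table


def write_species_table(table: SpeciesTable, path: str | Path, totals: bool = True) -> None:
    df = table.frame.reset_index().rename(columns={"index": "species"})
    if "species" not in df.columns:
        df = df.rename(columns={df.columns[0]: "species"})
    rows = [df]
    if totals:
        for wt in ("hardwood", "softwood"):
            a, v = table.subtotal(wt)
            rows.append(pd.DataFrame([{"species": f"Total {wt}", "area_km2": a,
                                       "volume_Mm3": v, "wood_type": wt}]))
        rows.append(pd.DataFrame([{"species": "Total", "area_km2": table.total_area_km2(),
                                   "volume_Mm3": table.total_volume_Mm3(), "wood_type": ""}]))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def default_species_table() -> SpeciesTable:
    """The shipped national species table (14 species + 'other' pools)."""
    path = Path(__file__).parent / "data" / "species_table.csv"
    return read_species_table(path)


def upscale(
    plots: Iterable[PlotState],
    species_table: SpeciesTable,
    variables: tuple[str, ...] = ("V",),
) -> pd.DataFrame:
    """Upscale per-ha plot variables to national per-species totals.

    For each species × region cell, the equal-weight mean of each
    per-hectare variable is multiplied by the area of the cell.  Cell
    areas split the species' reported area proportionally to the plot
    count of each region (the region-level area report of the source
    inventory is not part of the data model).  Cells with no plots
    contribute 0 and are flagged in the ``n_plots`` column.

    Returns a frame indexed by species with one ``<var>_total_m3`` column
    per requested variable (per-ha unit × ha) plus ``area_ha``.
    """
    df = plots_to_frame(plots)
    if df.empty:
        raise ValidationError("no plots to upscale")
    unknown = set(df["main_species"]) - set(species_table.species)
    if unknown:
        raise UnmappedSpeciesError(f"species not in species table: {sorted(unknown)}")
    out = []
    for species, sdf in df.groupby("main_species", sort=True):
        area_ha = species_table.area_km2(species) * 100.0  # km² -> ha
        counts = sdf.groupby("region").size()
        cell_area = counts / counts.sum() * area_ha
        rec: dict[str, object] = {"species": species, "area_ha": area_ha,
                                  "n_plots": int(len(sdf))}
        for var in variables:
            cell_mean = sdf.groupby("region")[var].mean()
            rec[f"{var}_total_m3"] = float((cell_mean * cell_area).sum())
        out.append(rec)
    return pd.DataFrame(out).set_index("species")
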