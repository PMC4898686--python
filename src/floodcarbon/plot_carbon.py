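"""Plot-level above-ground carbon estimation and categorical class assignment.

Converts tree inventories (DBH >= 10 cm, wood density) to per-hectare
carbon density via a DBH-and-density allometric model for tropical
forest, then bins the density into six broad carbon-stock classes whose
mid-points drive all downstream landscape accounting.

The allometry deliberately omits tree height: regional inventories
typically record species and DBH only, and the coarse class binning
absorbs most of the resulting per-tree error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Conventional default wood density (g/cm^3) when a species is not in
#: the lookup table; conservative for mixed tropical stands.
DEFAULT_WOOD_DENSITY = 0.5

#: Fraction of above-ground biomass assumed to be carbon.
DEFAULT_CARBON_FRACTION = 0.5

DBH_FLOOR_CM = 10.0


class DomainError(ValueError):
    """Raised for physically meaningless inputs (non-positive DBH etc.)."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem.

    Parameters
    ----------
    dbh_cm : float
        Diameter at breast height, centimetres; measurement floor 10 cm.
    wood_density : float
        Wood specific gravity, g/cm^3.
    species_label : str, optional
        Free-text species or genus name (used only for density lookup).
    """

    dbh_cm: float
    wood_density: float
    species_label: str = ""

    def __post_init__(self):
        if self.dbh_cm < DBH_FLOOR_CM:
            raise DomainError(f"DBH {self.dbh_cm} below {DBH_FLOOR_CM} cm floor")
        if self.wood_density <= 0:
            raise DomainError("wood density must be positive")


@dataclass
class PlotInventory:
    """A forest mensuration plot: an area in hectares plus its stems."""

    plot_id: str
    area_ha: float
    trees: list[TreeRecord] = field(default_factory=list)
    habitat_label: str = ""

    def __post_init__(self):
        if self.area_ha <= 0:
            raise DomainError("plot area must be positive")


@dataclass(frozen=True)
class CarbonClass:
    """Half-open density interval [lower, upper) with its accounting mid-point."""

    index: int
    lower_mgc: float
    upper_mgc: float  # math.inf for the open-ended top class
    midpoint_mgc: float

    def contains(self, mgc_per_ha: float) -> bool:
        return self.lower_mgc <= mgc_per_ha < self.upper_mgc


#: The six-class scheme: <50, 50-100, 100-200, 200-300, 300-400, >400
#: MgC/ha with mid-points 25..450 (450 is a conservative stand-in for
#: the unbounded top class).
CARBON_CLASSES: tuple[CarbonClass, ...] = (
    CarbonClass(1, 0.0, 50.0, 25.0),
    CarbonClass(2, 50.0, 100.0, 75.0),
    CarbonClass(3, 100.0, 200.0, 150.0),
    CarbonClass(4, 200.0, 300.0, 250.0),
    CarbonClass(5, 300.0, 400.0, 350.0),
    CarbonClass(6, 400.0, math.inf, 450.0),
)

CLASS_MIDPOINTS: dict[int, float] = {c.index: c.midpoint_mgc for c in CARBON_CLASSES}


def tree_agb(dbh_cm: float, wood_density: float) -> float:
    """Above-ground biomass of one stem, in kg.

    Height-free moist-tropical-forest allometry in DBH ``D`` (cm) and
    wood density ``rho`` (g/cm^3)::

        AGB = rho * exp(-1.499 + 2.148 ln D + 0.207 (ln D)^2 - 0.02081 (ln D)^3)

    Accepts scalars or numpy arrays.
    """
    d = np.asarray(dbh_cm, dtype=float)
    rho = np.asarray(wood_density, dtype=float)
    if np.any(d <= 0) or np.any(rho <= 0):
        raise DomainError("DBH and wood density must be positive")
    ln_d = np.log(d)
    agb = rho * np.exp(-1.499 + 2.148 * ln_d + 0.207 * ln_d**2 - 0.02081 * ln_d**3)
    if agb.ndim == 0:
        return float(agb)
    return agb


def default_density(
    species_label: str, density_table: Mapping[str, float] | None = None
) -> float:
    """Wood density for a species label, falling back to 0.5 g/cm^3."""
    if density_table:
        return float(density_table.get(species_label, DEFAULT_WOOD_DENSITY))
    return DEFAULT_WOOD_DENSITY


def plot_carbon_density(
    plot: PlotInventory, carbon_fraction: float = DEFAULT_CARBON_FRACTION
) -> float:
    """Carbon density of a plot in MgC/ha.

    Sums per-tree AGB (kg), converts to Mg, applies the biomass-to-carbon
    fraction, and divides by plot area.
    """
    if plot.area_ha <= 0:
        raise DomainError("plot area must be positive")
    if not plot.trees:
        return 0.0
    total_kg = sum(tree_agb(t.dbh_cm, t.wood_density) for t in plot.trees)
    return (total_kg / 1000.0) * carbon_fraction / plot.area_ha


def assign_carbon_class(mgc_per_ha: float) -> CarbonClass:
    """Map a carbon density to its class; intervals are lower-inclusive."""
    if mgc_per_ha < 0:
        raise DomainError("carbon density cannot be negative")
    for cls in CARBON_CLASSES:
        if cls.contains(mgc_per_ha):
            return cls
    raise DomainError(f"no class for density {mgc_per_ha}")  # pragma: no cover


def inventory_carbon_table(
    plots: Iterable[PlotInventory],
    carbon_fraction: float = DEFAULT_CARBON_FRACTION,
) -> pd.DataFrame:
    """Per-plot density and class as a tidy frame (plot_id, mgc_per_ha, carbon_class)."""
    rows = []
    for plot in plots:
        dens = plot_carbon_density(plot, carbon_fraction)
        rows.append(
            {
                "plot_id": plot.plot_id,
                "mgc_per_ha": dens,
                "carbon_class": assign_carbon_class(dens).index,
            }
        )
    return pd.DataFrame(rows, columns=["plot_id", "mgc_per_ha", "carbon_class"])


def plots_from_frame(
    trees: pd.DataFrame,
    plot_areas: Mapping[str, float] | pd.Series,
    density_table: Mapping[str, float] | None = None,
) -> list[PlotInventory]:
    """Assemble PlotInventory objects from a tree table.

    ``trees`` needs columns plot_id, dbh_cm and either wood_density or
    species (resolved through ``density_table`` with the 0.5 fallback).
    """
    out = []
    for pid, grp in trees.groupby("plot_id", sort=True):
        records = []
        for _, row in grp.iterrows():
            if "wood_density" in grp.columns and not pd.isna(row.get("wood_density")):
                rho = float(row["wood_density"])
            else:
                rho = default_density(str(row.get("species", "")), density_table)
            records.append(
                TreeRecord(float(row["dbh_cm"]), rho, str(row.get("species", "")))
            )
        out.append(PlotInventory(str(pid), float(plot_areas[pid]), records))
    return out
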