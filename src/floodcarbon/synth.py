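"""Synthetic inputs: tree inventories, stratified landscapes, palm age series.

The generator emulates the statistical structure of the study inputs so
the whole pipeline is testable without field data:

* a plot inventory whose stems have truncated log-normal DBH (floor
  10 cm, the measurement threshold) and uniform wood density;
* a stratified landscape whose per-carbon-class extents match the
  configured marginals exactly, with suitability and tenure spread
  proportionally (a product/independence allocation — the real joint
  distribution of class x suitability is not published, so independence
  is the neutral choice);
* a per-palm carbon age series following a saturating growth curve,
  observed only at configurable ages (the default gap set reproduces an
  11-age-category field campaign spanning years 2-19).

One integer seed drives all stochastic draws; regeneration with the
same seed is bit-identical.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .accounting import SUITABILITY_CLASSES, TENURE_CLASSES
from .plot_carbon import CLASS_MIDPOINTS, DBH_FLOOR_CM, PlotInventory, TreeRecord
from .reference import MAX_OBSERVED_AGE, PalmAgeSeries


class ConfigError(ValueError):
    """Inconsistent or physically invalid generator configuration."""


#: Default per-carbon-class extents (ha) of the unprotected forest.
DEFAULT_CLASS_EXTENTS_HA = {1: 4249, 2: 3989, 3: 15387, 4: 3851, 5: 1841, 6: 856}

#: Default oil-palm suitability extents (ha) of the same landscape.
DEFAULT_SUITABILITY_EXTENTS_HA = {
    "full_stand": 9327,
    "under50": 4352,
    "under25": 16492,
}

#: Default tenure mix, as fractions of the landscape (derived from the
#: tenure split of unprotected-forest carbon stock).
_TENURE_MGC = {
    "native_title": 1_376_453,
    "country_lease": 1_602_923,
    "state_demarcated": 590_908,
    "state_undemarcated": 1_135_618,
}
DEFAULT_TENURE_FRACTIONS = {
    k: v / sum(_TENURE_MGC.values()) for k, v in _TENURE_MGC.items()
}

#: Ages with no field observations in the default palm campaign; the
#: remaining observed ages are {2-5, 7-8, 13, 15-16, 18-19}.
DEFAULT_PALM_GAPS = (1, 6, 9, 10, 11, 12, 14, 17)

_SPECIES_POOL = (
    "Dipterocarpus sp.",
    "Shorea sp.",
    "Eusideroxylon zwageri",
    "Octomeles sumatrana",
    "Nauclea sp.",
    "unknown",
)


class SyntheticConfig(BaseModel):
    """All knobs of the synthetic generators, with study-scale defaults."""

    seed: int = 0
    n_plots: int = Field(default=230, ge=1)
    trees_per_plot: float = Field(default=50.0, gt=0)
    plot_area_ha: float = Field(default=110.0 / 230.0, gt=0)
    dbh_lognormal_params: tuple[float, float] = (float(np.log(25.0)), 0.5)
    wood_density_range: tuple[float, float] = (0.4, 0.8)
    class_extents_ha: dict[int, float] = Field(
        default_factory=lambda: dict(DEFAULT_CLASS_EXTENTS_HA)
    )
    suitability_extents_ha: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SUITABILITY_EXTENTS_HA)
    )
    tenure_fractions: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TENURE_FRACTIONS)
    )
    marginal_tolerance_ha: float = Field(default=5.0, ge=0)
    palm_series_gaps: tuple[int, ...] = DEFAULT_PALM_GAPS
    palm_asymptote_mgc: float = Field(default=0.49, gt=0)
    palm_growth_rate: float = Field(default=0.12, gt=0)

    @field_validator("dbh_lognormal_params")
    @classmethod
    def _sigma_positive(cls, v):
        if v[1] <= 0:
            raise ValueError("log-DBH sigma must be positive")
        return v

    @field_validator("wood_density_range")
    @classmethod
    def _density_range(cls, v):
        lo, hi = v
        if lo <= 0 or hi < lo:
            raise ValueError("wood density range must satisfy 0 < min <= max")
        return v

    @field_validator("class_extents_ha", "suitability_extents_ha")
    @classmethod
    def _extents_nonneg(cls, v):
        if any(e < 0 for e in v.values()):
            raise ValueError("extents must be non-negative")
        return v

    @field_validator("class_extents_ha")
    @classmethod
    def _classes_known(cls, v):
        bad = set(v) - set(CLASS_MIDPOINTS)
        if bad:
            raise ValueError(f"unknown carbon classes {sorted(bad)}")
        return v

    @field_validator("suitability_extents_ha")
    @classmethod
    def _suitability_known(cls, v):
        bad = set(v) - set(SUITABILITY_CLASSES)
        if bad:
            raise ValueError(f"unknown suitability classes {sorted(bad)}")
        return v

    @field_validator("tenure_fractions")
    @classmethod
    def _tenure_valid(cls, v):
        bad = set(v) - set(TENURE_CLASSES)
        if bad:
            raise ValueError(f"unknown tenure classes {sorted(bad)}")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("tenure fractions must sum to 1")
        return v

    @field_validator("palm_series_gaps")
    @classmethod
    def _gaps_in_range(cls, v):
        if any(not (1 <= g <= MAX_OBSERVED_AGE) for g in v):
            raise ValueError(f"gaps must lie within 1..{MAX_OBSERVED_AGE}")
        return tuple(sorted(set(v)))


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, size: int, floor: float
) -> np.ndarray:
    """Log-normal draws conditioned on >= floor, by rejection."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mu, sigma, size=max(size - filled, 16))
        keep = draw[draw >= floor][: size - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_inventory(config: SyntheticConfig) -> list[PlotInventory]:
    """Draw a plot inventory: Poisson stem counts, truncated log-normal DBH."""
    mu, sigma = config.dbh_lognormal_params
    lo, hi = config.wood_density_range
    rng = np.random.default_rng(config.seed)
    plots = []
    for i in range(config.n_plots):
        n_trees = int(rng.poisson(config.trees_per_plot))
        dbh = _truncated_lognormal(rng, mu, sigma, n_trees, DBH_FLOOR_CM)
        rho = rng.uniform(lo, hi, size=n_trees) if hi > lo else np.full(n_trees, lo)
        species = rng.choice(_SPECIES_POOL, size=n_trees)
        trees = [
            TreeRecord(float(d), float(r), str(s))
            for d, r, s in zip(dbh, rho, species)
        ]
        plots.append(PlotInventory(f"plot{i:04d}", config.plot_area_ha, trees))
    return plots


def inventory_to_frame(plots: list[PlotInventory]) -> pd.DataFrame:
    """Flatten an inventory to a tree table (one row per stem)."""
    rows = [
        {
            "plot_id": p.plot_id,
            "tree_id": f"{p.plot_id}_t{j:04d}",
            "dbh_cm": t.dbh_cm,
            "wood_density": t.wood_density,
            "species": t.species_label,
        }
        for p in plots
        for j, t in enumerate(p.trees)
    ]
    return pd.DataFrame(
        rows, columns=["plot_id", "tree_id", "dbh_cm", "wood_density", "species"]
    )


def generate_landscape(config: SyntheticConfig) -> pd.DataFrame:
    """Build strata whose carbon-class marginals equal the configured extents.

    Each carbon class extent is split across suitability classes in
    proportion to the suitability marginals, then across tenures by the
    tenure fractions, yielding one stratum per non-empty combination.
    Class marginals are exact; suitability marginals are matched up to
    the (small) mismatch between the two configured totals, which must
    itself be within ``marginal_tolerance_ha``.
    """
    class_total = sum(config.class_extents_ha.values())
    suit_total = sum(config.suitability_extents_ha.values())
    if not config.class_extents_ha or not config.suitability_extents_ha:
        return pd.DataFrame(
            columns=["stratum_id", "extent_ha", "carbon_class", "suitability", "tenure"]
        )
    if abs(class_total - suit_total) > config.marginal_tolerance_ha:
        raise ConfigError(
            f"carbon-class total {class_total} ha and suitability total "
            f"{suit_total} ha disagree by more than "
            f"{config.marginal_tolerance_ha} ha"
        )
    suit_frac = {s: e / suit_total for s, e in config.suitability_extents_ha.items()}
    rows = []
    for cls in sorted(config.class_extents_ha):
        cls_extent = config.class_extents_ha[cls]
        if cls_extent == 0:
            continue
        for suit in sorted(suit_frac):
            for tenure in sorted(config.tenure_fractions):
                extent = cls_extent * suit_frac[suit] * config.tenure_fractions[tenure]
                if extent <= 0:
                    continue
                rows.append(
                    {
                        "stratum_id": f"c{cls}_{suit}_{tenure}",
                        "extent_ha": extent,
                        "carbon_class": cls,
                        "suitability": suit,
                        "tenure": tenure,
                    }
                )
    return pd.DataFrame(rows)


def generate_palm_series(config: SyntheticConfig) -> PalmAgeSeries:
    """Per-palm carbon observations following a saturating growth curve.

    The default asymptote/rate put the implied full-capacity reference
    level near the published mid-40s MgC/ha.  Ages listed in
    ``palm_series_gaps`` are omitted from the observations.
    """
    gaps = set(config.palm_series_gaps)
    observed_ages = [a for a in range(1, MAX_OBSERVED_AGE + 1) if a not in gaps]
    if not observed_ages:
        raise ConfigError("all ages gapped: nothing to interpolate from")
    M, k = config.palm_asymptote_mgc, config.palm_growth_rate
    observed = {a: float(M * (1.0 - np.exp(-k * a))) for a in observed_ages}
    return PalmAgeSeries(observed=observed)
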