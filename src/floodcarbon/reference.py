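"""Oil-palm carbon reference levels.

REDD+ credits only the carbon *above* the counterfactual land use, so
the baseline is the time-averaged above-ground carbon of an oil-palm
planting over its 25-year crop life.  Field data typically observe only
a subset of ages; this module completes a partially observed per-palm
age series and converts it to a per-hectare reference by suitability
class.

Completion rules
----------------
* a single interior gap takes the mean of its flanking observed years;
* a run of consecutive gaps is filled by equal annual increments
  (linear interpolation between flanking observations);
* ages before the first observation are back-filled with the first
  observed value (conservative: slightly overstates early-palm carbon);
* ages beyond the last observation, out to the 25-year lifespan, hold
  the last observed value (again conservative for the baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plot_carbon import DomainError

LIFESPAN_YR = 25
MAX_OBSERVED_AGE = 19

#: Maximum planting densities (palms/ha) per oil-palm suitability class:
#: full capacity, half capacity, quarter capacity.
PALMS_PER_HA = {"full_stand": 136, "under50": 68, "under25": 34}

#: Published reference levels (MgC/ha) used by default in the economics.
#: Note the degraded-class values are *not* proportional scalings of the
#: full-stand value; they are retained as printed constants and can be
#: overridden with a freshly computed reference.
DEFAULT_REFERENCE_MGC_HA = {"full_stand": 46.0, "under50": 20.0, "under25": 7.0}


@dataclass
class PalmAgeSeries:
    """Per-palm carbon (MgC) by palm age in years, possibly with gaps."""

    observed: dict[int, float] = field(default_factory=dict)
    lifespan_yr: int = LIFESPAN_YR

    def __post_init__(self):
        for age, val in self.observed.items():
            if not (1 <= age <= MAX_OBSERVED_AGE):
                raise DomainError(f"observed age {age} outside 1..{MAX_OBSERVED_AGE}")
            if val < 0:
                raise DomainError("per-palm carbon cannot be negative")


def complete_series(series: PalmAgeSeries) -> np.ndarray:
    """Fill a gapped age series out to the full crop lifespan.

    Returns an array of length ``lifespan_yr`` indexed by age-1
    (element 0 is age 1).  Observed values are reproduced exactly.
    """
    obs = dict(sorted(series.observed.items()))
    if len(obs) < 2:
        raise DomainError("need at least two observed ages to complete a series")
    ages = np.array(list(obs.keys()), dtype=float)
    vals = np.array(list(obs.values()), dtype=float)
    out = np.empty(series.lifespan_yr, dtype=float)
    first_age, last_age = int(ages[0]), int(ages[-1])
    for year in range(1, series.lifespan_yr + 1):
        if year in obs:
            out[year - 1] = obs[year]
        elif year < first_age:
            out[year - 1] = vals[0]
        elif year > last_age:
            out[year - 1] = vals[-1]
        else:
            # np.interp gives the equal-increment fill for gap runs and
            # the flanking-mean for single gaps in one rule.
            out[year - 1] = np.interp(year, ages, vals)
    return out


def time_averaged_reference(complete: np.ndarray, palms_per_ha: float) -> float:
    """Time-averaged per-hectare reference level (MgC/ha).

    Mean per-palm carbon over the crop lifespan, scaled by planting
    density.
    """
    complete = np.asarray(complete, dtype=float)
    if complete.shape[0] != LIFESPAN_YR:
        raise DomainError(f"expected a {LIFESPAN_YR}-year series")
    return float(complete.mean() * palms_per_ha)


def reference_levels_from_series(
    series: PalmAgeSeries, palms_per_ha: dict[str, int] | None = None
) -> dict[str, float]:
    """Compute a per-suitability reference table from one palm series."""
    palms = palms_per_ha or PALMS_PER_HA
    filled = complete_series(series)
    return {suit: time_averaged_reference(filled, n) for suit, n in palms.items()}
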