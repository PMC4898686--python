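"""Mid-point carbon-stock accounting over landscape strata.

A stratum is an accounting unit (carbon class x oil-palm suitability x
tenure) with an extent in hectares.  Stocks are extent times the class
mid-point, so totals are exact integer arithmetic whenever extents are
integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .plot_carbon import CLASS_MIDPOINTS, DomainError

SUITABILITY_CLASSES = ("full_stand", "under50", "under25")
TENURE_CLASSES = (
    "native_title",
    "country_lease",
    "state_demarcated",
    "state_undemarcated",
    "protected",
    "other",
)

STRATA_COLUMNS = ["stratum_id", "extent_ha", "carbon_class", "suitability", "tenure"]


@dataclass(frozen=True)
class Stratum:
    stratum_id: str
    extent_ha: float
    carbon_class: int
    suitability: str
    tenure: str

    def __post_init__(self):
        if self.extent_ha < 0:
            raise DomainError("extent must be non-negative")
        if self.carbon_class not in CLASS_MIDPOINTS:
            raise DomainError(f"unknown carbon class {self.carbon_class}")
        if self.suitability not in SUITABILITY_CLASSES:
            raise DomainError(f"unknown suitability {self.suitability!r}")
        if self.tenure not in TENURE_CLASSES:
            raise DomainError(f"unknown tenure {self.tenure!r}")


def stratum_carbon(extent_ha: float, carbon_class: int) -> float:
    """Carbon stock (MgC) of one stratum: extent times the class mid-point."""
    if extent_ha < 0:
        raise DomainError("extent must be non-negative")
    try:
        mid = CLASS_MIDPOINTS[int(carbon_class)]
    except (KeyError, ValueError) as exc:
        raise DomainError(f"unknown carbon class {carbon_class!r}") from exc
    return extent_ha * mid


def strata_frame(strata: Iterable[Stratum] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a stratum collection to a validated DataFrame."""
    if isinstance(strata, pd.DataFrame):
        df = strata.copy()
        missing = set(STRATA_COLUMNS) - set(df.columns)
        if missing:
            raise DomainError(f"strata table missing columns: {sorted(missing)}")
    else:
        df = pd.DataFrame(
            [
                {
                    "stratum_id": s.stratum_id,
                    "extent_ha": s.extent_ha,
                    "carbon_class": s.carbon_class,
                    "suitability": s.suitability,
                    "tenure": s.tenure,
                }
                for s in strata
            ],
            columns=STRATA_COLUMNS,
        )
    if len(df):
        if (df["extent_ha"] < 0).any():
            raise DomainError("negative stratum extent")
        bad = set(df["carbon_class"].astype(int)) - set(CLASS_MIDPOINTS)
        if bad:
            raise DomainError(f"unknown carbon classes {sorted(bad)}")
    return df


def landscape_totals(
    strata: Iterable[Stratum] | pd.DataFrame,
    group_by: Literal[None, "carbon_class", "tenure", "suitability"] = None,
) -> pd.DataFrame:
    """Extent and carbon totals, optionally grouped.

    Ungrouped, returns a single-row frame of grand totals; grouped,
    one row per group value.  Carbon is mid-point arithmetic, unrounded.
    """
    df = strata_frame(strata)
    if df.empty:
        base = pd.DataFrame({"extent_ha": [0.0], "total_mgc": [0.0]})
        return base if group_by is None else base.iloc[0:0]
    df = df.assign(
        total_mgc=[
            stratum_carbon(e, c) for e, c in zip(df["extent_ha"], df["carbon_class"])
        ]
    )
    if group_by is None:
        return pd.DataFrame(
            {
                "extent_ha": [df["extent_ha"].sum()],
                "total_mgc": [df["total_mgc"].sum()],
            }
        )
    out = (
        df.groupby(group_by, sort=True)[["extent_ha", "total_mgc"]]
        .sum()
        .reset_index()
    )
    return out


def mean_density(strata: Iterable[Stratum] | pd.DataFrame) -> float:
    """Area-weighted mean carbon density (MgC/ha) of a landscape."""
    totals = landscape_totals(strata)
    extent = float(totals["extent_ha"].iloc[0])
    if extent <= 0:
        raise DomainError("mean density undefined for zero total extent")
    return float(totals["total_mgc"].iloc[0]) / extent


def class_report(strata: Iterable[Stratum] | pd.DataFrame) -> pd.DataFrame:
    """Per-carbon-class extent/stock report with mid-points and a total row."""
    by_class = landscape_totals(strata, group_by="carbon_class")
    by_class["midpoint_mgc_ha"] = by_class["carbon_class"].map(CLASS_MIDPOINTS)
    total = pd.DataFrame(
        {
            "carbon_class": ["total"],
            "extent_ha": [by_class["extent_ha"].sum()],
            "total_mgc": [by_class["total_mgc"].sum()],
            "midpoint_mgc_ha": [float("nan")],
        }
    )
    cols = ["carbon_class", "midpoint_mgc_ha", "extent_ha", "total_mgc"]
    return pd.concat([by_class, total], ignore_index=True)[cols]


def tenure_report(strata: Iterable[Stratum] | pd.DataFrame) -> pd.DataFrame:
    """Per-tenure carbon stock report with a total row."""
    by_tenure = landscape_totals(strata, group_by="tenure")
    total = pd.DataFrame(
        {
            "tenure": ["total"],
            "extent_ha": [by_tenure["extent_ha"].sum()],
            "total_mgc": [by_tenure["total_mgc"].sum()],
        }
    )
    return pd.concat([by_tenure, total], ignore_index=True)
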