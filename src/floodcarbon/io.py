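"""Flat-file I/O: inventory/landscape/palm-series CSV and GeoJSON strata.

All tables are plain CSV with fixed column names so runs are diff-able.
Strata can optionally round-trip through GeoJSON; geometry is decorative
(the analysis only uses the property tuple), so features written without
geometry carry ``"geometry": null``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .accounting import STRATA_COLUMNS
from .reference import PalmAgeSeries


def write_landscape_csv(strata: pd.DataFrame, path) -> None:
    strata.to_csv(path, index=False, columns=STRATA_COLUMNS)


def read_landscape_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["carbon_class"] = df["carbon_class"].astype(int)
    return df


def write_landscape_geojson(strata: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": None,
            "properties": {
                "stratum_id": row.stratum_id,
                "extent_ha": row.extent_ha,
                "carbon_class": int(row.carbon_class),
                "suitability": row.suitability,
                "tenure": row.tenure,
            },
        }
        for row in strata.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_landscape_geojson(path) -> pd.DataFrame:
    data = json.loads(Path(path).read_text())
    rows = [f["properties"] for f in data["features"]]
    df = pd.DataFrame(rows, columns=STRATA_COLUMNS)
    if len(df):
        df["carbon_class"] = df["carbon_class"].astype(int)
    return df


def write_palm_series_csv(series: PalmAgeSeries, path) -> None:
    pd.DataFrame(
        {"age_yr": list(series.observed), "mgc_per_palm": list(series.observed.values())}
    ).to_csv(path, index=False)


def read_palm_series_csv(path) -> PalmAgeSeries:
    df = pd.read_csv(path)
    return PalmAgeSeries(
        observed={int(a): float(v) for a, v in zip(df["age_yr"], df["mgc_per_palm"])}
    )


def read_inventory_csv(path) -> pd.DataFrame:
    """Tree table: plot_id, tree_id, dbh_cm, wood_density, species."""
    return pd.read_csv(path)


def read_density_table_csv(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return dict(zip(df["species_label"].astype(str), df["wood_density"].astype(float)))
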