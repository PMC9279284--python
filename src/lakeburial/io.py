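"""Delimited-text I/O for core profiles and lake tables.

All tables are headered CSV with fixed column names; missing values are
empty fields.  Core profile schema (one row per interval, surface first):

    lake_id, collection_year, top_depth_cm, thickness_cm, dry_bulk_density,
    pb210_total, pb210_total_err, ra226, oc_percent, d13c, cn_molar

with the last three optional.  Lake tables use
``lake_id, latitude, longitude, biome, land_cover, annual_temp, burial``
(plus any extra covariates, passed through untouched).
"""

from __future__ import annotations

import math

import pandas as pd

from .geochron import CoreInterval, CoreProfile, DatedProfile

__all__ = [
    "read_core_profile",
    "write_core_profile",
    "write_dated_profile",
    "read_lake_table",
]

_CORE_REQUIRED = [
    "top_depth_cm",
    "thickness_cm",
    "dry_bulk_density",
    "pb210_total",
    "ra226",
    "oc_percent",
]


def _opt(row, name):
    v = row.get(name)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_core_profile(path) -> CoreProfile:
    """Read one core profile from CSV (schema in the module docstring)."""
    df = pd.read_csv(path)
    missing = [c for c in _CORE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    intervals = []
    for _, row in df.iterrows():
        intervals.append(
            CoreInterval(
                top_depth=float(row["top_depth_cm"]),
                thickness=float(row["thickness_cm"]),
                dry_bulk_density=float(row["dry_bulk_density"]),
                pb210_total=float(row["pb210_total"]),
                ra226=float(row["ra226"]),
                oc_percent=float(row["oc_percent"]),
                pb210_total_err=_opt(row, "pb210_total_err") or 0.0,
                d13c=_opt(row, "d13c"),
                cn_molar=_opt(row, "cn_molar"),
            )
        )
    lake_id = str(df["lake_id"].iloc[0]) if "lake_id" in df.columns else "core"
    year = int(df["collection_year"].iloc[0]) if "collection_year" in df.columns else 0
    return CoreProfile(lake_id=lake_id, intervals=intervals, collection_year=year)


def write_core_profile(profile: CoreProfile, path) -> None:
    rows = []
    for iv in profile.intervals:
        rows.append(
            {
                "lake_id": profile.lake_id,
                "collection_year": profile.collection_year,
                "top_depth_cm": iv.top_depth,
                "thickness_cm": iv.thickness,
                "dry_bulk_density": iv.dry_bulk_density,
                "pb210_total": iv.pb210_total,
                "pb210_total_err": iv.pb210_total_err,
                "ra226": iv.ra226,
                "oc_percent": iv.oc_percent,
                "d13c": iv.d13c,
                "cn_molar": iv.cn_molar,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dated_profile(dated: DatedProfile, path) -> None:
    df = dated.to_frame()
    df.insert(0, "lake_id", dated.lake_id)
    df.insert(1, "model", dated.model)
    df.to_csv(path, index=False)


def read_lake_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["lake_id", "biome", "land_cover", "annual_temp", "burial"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df
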