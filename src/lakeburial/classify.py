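"""Lake classification into biome/land-use strata and forest-cover covariates.

Lakes are stratified into 10 classes: 7 natural terrestrial biomes, or —
when the surrounding land cover is human-altered (cropland, urban, paddy
field) — one of 3 anthropic classes cut by annual air temperature
(cold < 7.5 °C, moderate 7.5–15.0 °C, warm > 15 °C).

The satellite/GIS processing itself (biome polygons, land-cover rasters,
flood masks) is out of scope: this module consumes its outputs as tabular
attributes — per-lake land-cover labels, per-buffer pixel counts and
per-scene river water-level deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NATURAL_BIOMES",
    "ANTHROPIC_COVERS",
    "NATURAL_COVERS",
    "LakeRecord",
    "classify_lake",
    "classify_table",
    "filter_by_water_level",
    "forest_fraction",
    "COLD_MAX_C",
    "MODERATE_MAX_C",
    "DEFAULT_MAX_DEVIATION_PCT",
]

NATURAL_BIOMES = (
    "Humid tropical forest",
    "Other tropical/subtropical",
    "Temperate forest",
    "Boreal forest",
    "Other mid-latitude",
    "Subpolar and polar",
    "Deserts",
)

ANTHROPIC_CLASSES = ("Cold anthropic", "Moderate anthropic", "Warm anthropic")

ALL_CLASSES = NATURAL_BIOMES + ANTHROPIC_CLASSES

#: GLCNMO categories treated as human-altered
ANTHROPIC_COVERS = frozenset({"cropland", "urban", "paddy field"})

#: GLCNMO categories treated as natural
NATURAL_COVERS = frozenset(
    {
        "broadleaf evergreen forest",
        "broadleaf deciduous forest",
        "needleleaf evergreen forest",
        "needleleaf deciduous forest",
        "mixed forest",
        "tree open",
        "forest",
        "shrub",
        "herbaceous",
        "herbaceous with sparse tree/shrub",
        "sparse vegetation",
        "wetland",
        "bare area",
        "snow and ice",
        "water",
        "natural",
    }
)

# anthropic temperature bins (°C): cold < 7.5 <= moderate <= 15.0 < warm
COLD_MAX_C = 7.5
MODERATE_MAX_C = 15.0

#: river water-level scenes are accepted within ±8% of the long-term average
DEFAULT_MAX_DEVIATION_PCT = 8.0


@dataclass
class LakeRecord:
    """One lake's whole-lake burial rate plus classification covariates."""

    lake_id: str
    latitude: float = float("nan")
    longitude: float = float("nan")
    biome: str = ""
    land_cover: str = ""
    annual_temp: float = float("nan")  # °C
    burial: float = float("nan")  # g C m⁻² yr⁻¹
    max_depth: float | None = None  # m
    forest_fraction_by_buffer: dict[float, float] = field(default_factory=dict)
    lake_class: str | None = None

    def __post_init__(self) -> None:
        if not np.isnan(self.annual_temp) and not -30.0 <= self.annual_temp <= 40.0:
            raise ValueError(f"annual_temp out of range: {self.annual_temp} °C")
        if not np.isnan(self.burial) and self.burial < 0:
            raise ValueError(f"burial must be >= 0, got {self.burial}")
        for b, f in self.forest_fraction_by_buffer.items():
            if not 0.0 <= f <= 100.0:
                raise ValueError(f"forest fraction out of [0,100] at buffer {b}")


def _anthropic_class(annual_temp: float) -> str:
    if annual_temp < COLD_MAX_C:
        return "Cold anthropic"
    if annual_temp <= MODERATE_MAX_C:
        return "Moderate anthropic"
    return "Warm anthropic"


def classify_lake(record: LakeRecord) -> str:
    """Assign the lake to exactly one of the 10 strata.

    Human-altered land cover overrides the biome; natural lakes keep their
    biome label. Deterministic and total over valid inputs.
    """
    cover = record.land_cover.strip().lower()
    if cover in ANTHROPIC_COVERS:
        if np.isnan(record.annual_temp):
            raise ValueError(
                f"lake {record.lake_id!r}: anthropic classification needs annual_temp"
            )
        label = _anthropic_class(record.annual_temp)
    elif cover in NATURAL_COVERS:
        if record.biome not in NATURAL_BIOMES:
            raise ValueError(
                f"lake {record.lake_id!r}: unknown biome {record.biome!r}; "
                f"accepted: {', '.join(NATURAL_BIOMES)}"
            )
        label = record.biome
    else:
        accepted = sorted(ANTHROPIC_COVERS | NATURAL_COVERS)
        raise ValueError(
            f"lake {record.lake_id!r}: unknown land-cover label "
            f"{record.land_cover!r}; accepted: {', '.join(accepted)}"
        )
    record.lake_class = label
    return label


def classify_table(lakes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_lake` over a lakes table.

    Expects columns lake_id, biome, land_cover, annual_temp; returns a copy
    with a ``lake_class`` column appended.
    """
    out = lakes.copy()
    labels = []
    for row in out.itertuples(index=False):
        rec = LakeRecord(
            lake_id=str(row.lake_id),
            biome=getattr(row, "biome", ""),
            land_cover=getattr(row, "land_cover", ""),
            annual_temp=float(getattr(row, "annual_temp", float("nan"))),
        )
        labels.append(classify_lake(rec))
    out["lake_class"] = labels
    return out


def filter_by_water_level(
    scene_records, max_dev: float = DEFAULT_MAX_DEVIATION_PCT
):
    """Keep satellite scenes whose river water level was near the long-term mean.

    ``scene_records`` is an iterable of (scene_id, deviation %) pairs or a
    DataFrame with columns scene_id / deviation_pct.  Scenes with
    |deviation| ≤ ``max_dev`` (boundary inclusive) are kept.
    """
    if isinstance(scene_records, pd.DataFrame):
        dev = scene_records["deviation_pct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(dev)):
            raise ValueError("non-finite water-level deviation")
        return scene_records.loc[np.abs(dev) <= max_dev].reset_index(drop=True)
    kept = []
    for scene_id, dev in scene_records:
        if not np.isfinite(dev):
            raise ValueError(f"non-finite deviation for scene {scene_id!r}")
        if abs(dev) <= max_dev:
            kept.append((scene_id, dev))
    return kept


def forest_fraction(buffer_pixels: pd.DataFrame) -> pd.Series:
    """Percent non-flooded forest per buffer from classified pixel counts.

    ``buffer_pixels`` has columns buffer_km2, pixel_class, count where
    pixel_class is one of {forest, field, flooded, excluded}.  "excluded"
    pixels (the main river and its far margin) are dropped from the
    denominator entirely:  100 × forest / (forest + field + flooded).

    Buffers whose denominator is zero get NaN (flagged undefined).
    """
    df = buffer_pixels.copy()
    if (df["count"] < 0).any():
        raise ValueError("pixel counts must be >= 0")
    known = {"forest", "field", "flooded", "excluded"}
    bad = set(df["pixel_class"]) - known
    if bad:
        raise ValueError(f"unknown pixel classes {sorted(bad)}; accepted: {sorted(known)}")
    buffers = pd.Index(sorted(df["buffer_km2"].unique()), name="buffer_km2")
    df = df[df["pixel_class"] != "excluded"]
    tot = df.groupby("buffer_km2")["count"].sum().reindex(buffers, fill_value=0)
    forest = (
        df[df["pixel_class"] == "forest"].groupby("buffer_km2")["count"].sum()
    ).reindex(tot.index, fill_value=0)
    frac = 100.0 * forest / tot.where(tot > 0)
    frac.name = "forest_pct"
    return frac
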