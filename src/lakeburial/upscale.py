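"""Per-class burial summaries and area-weighted global carbon budgets.

Upscaling is stratified: each of the 10 lake classes gets an arithmetic
mean burial rate (g C m⁻² yr⁻¹) from its lakes, and the class flux is
mean × lake area.  The global sink is the sum of class fluxes and the
area-weighted mean burial is total flux / total area.  Classes with no
data (historically: other tropical/subtropical, deserts) contribute zero
flux and are reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClassSummary",
    "GlobalBudget",
    "summarize_classes",
    "upscale_global",
    "compare_to_emissions",
    "load_class_areas",
    "synthetic_class_areas",
    "G_M2_TO_TG_PER_KM2",
]

#: 1 g m⁻² yr⁻¹ over 1 km² = 1e6 g yr⁻¹ = 1e-6 Tg yr⁻¹
G_M2_TO_TG_PER_KM2 = 1e-6


@dataclass
class ClassSummary:
    """Burial statistics for one lake class (rates untransformed)."""

    label: str
    n: int
    mean: float  # g C m⁻² yr⁻¹
    se: float  # g C m⁻² yr⁻¹
    cv: float  # %
    area: float = float("nan")  # km²
    flagged_single: bool = False


@dataclass
class GlobalBudget:
    class_flux: dict[str, float]  # Tg C yr⁻¹
    total_flux: float  # Tg C yr⁻¹
    weighted_mean: float  # g C m⁻² yr⁻¹
    total_area: float  # km²

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"label": k, "flux_tg_yr": v} for k, v in self.class_flux.items()
        ]
        return pd.DataFrame(rows)


def summarize_classes(lakes: pd.DataFrame) -> list[ClassSummary]:
    """Mean, SE and CV of burial per lake class, on untransformed rates.

    ``lakes`` needs columns lake_class and burial.  SE = sd/√n with the
    n−1 denominator; a single-lake class reports SE 0 and is flagged.
    """
    if lakes["burial"].isna().any():
        raise ValueError("burial missing for some lakes")
    out: list[ClassSummary] = []
    for label, grp in lakes.groupby("lake_class", sort=False):
        rates = grp["burial"].to_numpy(dtype=float)
        n = rates.size
        mean = float(rates.mean())
        if n > 1:
            sd = float(rates.std(ddof=1))
            se = sd / np.sqrt(n)
            cv = 100.0 * sd / mean if mean > 0 else float("nan")
            out.append(ClassSummary(label, n, mean, se, cv))
        else:
            out.append(ClassSummary(label, 1, mean, 0.0, float("nan"), flagged_single=True))
    return out


def upscale_global(
    summaries: list[ClassSummary],
    areas: dict[str, float] | None = None,
) -> GlobalBudget:
    """Area-weight class means into per-class and total Tg C yr⁻¹ fluxes.

    ``areas`` (km² per class label) overrides any areas already set on the
    summaries.  Classes present in ``areas`` but without a summary (no
    burial data) contribute zero flux; their area still enters the
    area-weighted mean's denominator only if they have a mean — i.e. the
    weighted mean is total flux over the area of classes with data.
    """
    flux: dict[str, float] = {}
    total_area = 0.0
    for s in summaries:
        area = s.area
        if areas is not None and s.label in areas:
            area = float(areas[s.label])
        if not np.isfinite(area):
            raise ValueError(f"class {s.label!r} has no area")
        if area < 0:
            raise ValueError(f"negative area for class {s.label!r}")
        flux[s.label] = s.mean * area * G_M2_TO_TG_PER_KM2
        total_area += area
    if areas is not None:
        for label, area in areas.items():
            if label not in flux:
                if area < 0:
                    raise ValueError(f"negative area for class {label!r}")
                flux[label] = 0.0  # no data: zero flux, excluded from weighting
    total_flux = float(sum(flux.values()))
    weighted = total_flux / (total_area * G_M2_TO_TG_PER_KM2) if total_area > 0 else float("nan")
    return GlobalBudget(flux, total_flux, weighted, total_area)


def compare_to_emissions(
    burial_flux: float, combined_emission: float, lake_fraction: float = 0.913
) -> tuple[float, float]:
    """Burial sink as a percentage of lake-only CO₂ evasion.

    ``combined_emission`` (Tg C yr⁻¹) covers lakes plus reservoirs;
    ``lake_fraction`` is the lake share of that surface (0.913 for a
    3.0 Mkm² combined area of which 91.3% is lakes).  Returns
    (lake_emission Tg C yr⁻¹, burial as % of it).
    """
    if combined_emission <= 0:
        raise ValueError("combined_emission must be > 0")
    if not 0.0 < lake_fraction <= 1.0:
        raise ValueError("lake_fraction must be in (0, 1]")
    if burial_flux < 0:
        raise ValueError("burial_flux must be >= 0")
    lake_emission = lake_fraction * combined_emission
    return lake_emission, 100.0 * burial_flux / lake_emission


def load_class_areas(path_or_stream) -> dict[str, float]:
    """Read a class-area YAML ({areas_km2: {label: km²}})."""
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            cfg = yaml.safe_load(fh)
    return {str(k): float(v) for k, v in cfg["areas_km2"].items()}


def synthetic_class_areas() -> dict[str, float]:
    """Bundled SYNTHETIC class-area table (see the YAML header for caveats)."""
    ref = resources.files("lakeburial.data").joinpath("class_areas_synthetic.yaml")
    with ref.open() as fh:
        return load_class_areas(fh)
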