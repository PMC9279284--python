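"""Organic-matter source apportionment in (δ¹³C, C:N) space.

Surface-sediment samples are placed on the δ¹³C vs molar C:N plane and
assigned to rectangular endmember fields (C3 soil, C3 plants, C4 plants,
phytoplankton).  The apportionment is a simple box classification: the
fraction of samples falling in each box, plus an "unclassified" remainder
for points outside every box or inside more than one (ambiguous).

Box boundaries are literature conventions, not universal constants; they
ship as an overridable config (``data/endmembers_default.yaml``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .geochron import CoreProfile

__all__ = [
    "EndmemberBox",
    "EndmemberSet",
    "SedimentSignature",
    "load_endmembers",
    "default_endmembers",
    "surface_signature",
    "apportion_sources",
    "UNCLASSIFIED",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class EndmemberBox:
    """A rectangular source field; boundary points count as inside."""

    label: str
    d13c_min: float
    d13c_max: float
    cn_min: float
    cn_max: float

    def __post_init__(self) -> None:
        if not (self.d13c_min < self.d13c_max and self.cn_min < self.cn_max):
            raise ValueError(f"empty endmember box {self.label!r}")

    def contains(self, d13c, cn):
        d13c = np.asarray(d13c, dtype=float)
        cn = np.asarray(cn, dtype=float)
        return (
            (d13c >= self.d13c_min)
            & (d13c <= self.d13c_max)
            & (cn >= self.cn_min)
            & (cn <= self.cn_max)
        )


@dataclass(frozen=True)
class EndmemberSet:
    boxes: tuple[EndmemberBox, ...]

    def __post_init__(self) -> None:
        labels = [b.label for b in self.boxes]
        if len(set(labels)) != len(labels):
            raise ValueError("endmember labels must be unique")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.boxes)

    def __getitem__(self, label: str) -> EndmemberBox:
        for b in self.boxes:
            if b.label == label:
                return b
        raise KeyError(label)

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.boxes):
            for b in self.boxes[i + 1 :]:
                if (
                    a.d13c_min <= b.d13c_max
                    and b.d13c_min <= a.d13c_max
                    and a.cn_min <= b.cn_max
                    and b.cn_min <= a.cn_max
                ):
                    out.append((a.label, b.label))
        return out


@dataclass
class SedimentSignature:
    """Bulk (δ¹³C, C:N) of one lake's surface sediment."""

    lake_id: str
    d13c: float  # ‰ vs VPDB
    cn_molar: float

    def __post_init__(self) -> None:
        if not -45.0 <= self.d13c <= 0.0:
            raise ValueError(f"d13c out of plausible range: {self.d13c} ‰")
        if self.cn_molar <= 0:
            raise ValueError(f"cn_molar must be > 0, got {self.cn_molar}")


def load_endmembers(path_or_stream) -> EndmemberSet:
    """Read an endmember config (YAML, see data/endmembers_default.yaml)."""
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            cfg = yaml.safe_load(fh)
    boxes = []
    for label, spec in cfg["endmembers"].items():
        d = spec["d13c"]
        c = spec["cn"]
        boxes.append(EndmemberBox(str(label), float(d[0]), float(d[1]), float(c[0]), float(c[1])))
    return EndmemberSet(tuple(boxes))


def default_endmembers() -> EndmemberSet:
    ref = resources.files("lakeburial.data").joinpath("endmembers_default.yaml")
    with ref.open() as fh:
        return load_endmembers(fh)


def surface_signature(core: CoreProfile, top_cm: float = 6.0) -> SedimentSignature:
    """Thickness-weighted mean (δ¹³C, C:N) over intervals fully within ``top_cm``."""
    d13c, cn, w = [], [], []
    for iv in core.intervals:
        if iv.bottom_depth <= top_cm + 1e-9:
            if iv.d13c is None or iv.cn_molar is None:
                continue
            d13c.append(iv.d13c)
            cn.append(iv.cn_molar)
            w.append(iv.thickness)
    if not w:
        raise ValueError(
            f"core {core.lake_id!r}: no isotope data within the top {top_cm} cm"
        )
    w = np.asarray(w)
    return SedimentSignature(
        lake_id=core.lake_id,
        d13c=float(np.average(d13c, weights=w)),
        cn_molar=float(np.average(cn, weights=w)),
    )


def apportion_sources(
    signatures,
    endmembers: EndmemberSet | None = None,
) -> pd.Series:
    """Percent of samples per endmember box plus the unclassified remainder.

    ``signatures`` is a sequence of :class:`SedimentSignature` or a DataFrame
    with columns d13c / cn_molar.  A point inside two or more boxes is
    ambiguous and counted unclassified (no tie rule is assumed); boundary
    points count as inside.  The returned percentages, including
    ``unclassified``, sum to 100.
    """
    if endmembers is None:
        endmembers = default_endmembers()
    if isinstance(signatures, pd.DataFrame):
        d13c = signatures["d13c"].to_numpy(dtype=float)
        cn = signatures["cn_molar"].to_numpy(dtype=float)
    else:
        signatures = list(signatures)
        d13c = np.array([s.d13c for s in signatures], dtype=float)
        cn = np.array([s.cn_molar for s in signatures], dtype=float)
    n = d13c.size
    if n == 0:
        raise ValueError("no sediment signatures given")
    if endmembers.overlapping_pairs():
        warnings.warn(
            f"overlapping endmember boxes {endmembers.overlapping_pairs()}; "
            "points in the overlap are counted unclassified",
            stacklevel=2,
        )
    hits = np.stack([b.contains(d13c, cn) for b in endmembers.boxes])
    n_hits = hits.sum(axis=0)
    pct = {}
    for b, row in zip(endmembers.boxes, hits):
        pct[b.label] = 100.0 * np.sum(row & (n_hits == 1)) / n
    pct[UNCLASSIFIED] = 100.0 * np.sum(n_hits != 1) / n
    return pd.Series(pct, name="contribution_pct")
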