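"""Suitability classification, class-area bookkeeping, and habitat centroids.

Classes follow the four-level convention (0 unsuitable, 1 marginal,
2 moderate, 3 most) with half-open bins assigned upward: [0, 0.2),
[0.2, 0.5), [0.5, 0.7), [0.7, 1]. Percentages are rounded half away from
zero to the reported precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .grids import GridLayer

__all__ = [
    "SuitabilityClasses",
    "AreaTable",
    "HabitatCentroid",
    "classify",
    "area_table",
    "area_table_from_counts",
    "scenario_delta",
    "centroid",
    "centroid_shift",
    "round_half_away",
]

CLASS_LABELS = {0: "unsuitable", 1: "marginal", 2: "moderate", 3: "most"}


class SuitabilityError(ValueError):
    pass


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (report parity; banker's rounding differs)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class SuitabilityClasses:
    """Ordered cut points on (0, 1) separating the four classes."""

    cuts: Tuple[float, float, float] = (0.2, 0.5, 0.7)

    def __post_init__(self) -> None:
        c = self.cuts
        if len(c) != 3 or not (0 < c[0] < c[1] < c[2] < 1):
            raise SuitabilityError("cuts must be strictly increasing within (0,1)")


@dataclass
class AreaTable:
    """Per-class areas in km² plus the suitable total (classes 1–3)."""

    areas_km2: Dict[int, float]
    scenario: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.areas_km2) - set(CLASS_LABELS)
        if unknown:
            raise SuitabilityError(f"unknown class labels: {sorted(unknown)}")
        if any(a < 0 for a in self.areas_km2.values()):
            raise SuitabilityError("class areas must be non-negative")

    @property
    def total_suitable_km2(self) -> float:
        return sum(self.areas_km2.get(c, 0.0) for c in (1, 2, 3))

    def percentages(self) -> Dict[int, float]:
        """Share of each suitable class in the suitable total, to 1 decimal."""
        total = self.total_suitable_km2
        if total <= 0:
            raise SuitabilityError("no suitable area; percentages undefined")
        return {
            c: round_half_away(100.0 * self.areas_km2.get(c, 0.0) / total, 1)
            for c in (1, 2, 3)
        }

    def to_row(self) -> Dict[str, float]:
        row = {CLASS_LABELS[c]: self.areas_km2.get(c, 0.0) for c in sorted(CLASS_LABELS)}
        row["total_suitable"] = self.total_suitable_km2
        return row


@dataclass
class HabitatCentroid:
    x: float
    y: float
    mean_elevation: Optional[float] = None


def classify(suit: GridLayer, classes: SuitabilityClasses | None = None) -> GridLayer:
    """Bin continuous suitability in [0, 1] into classes 0–3."""
    if classes is None:
        classes = SuitabilityClasses()
    valid = suit.valid_mask
    vals = suit.values[valid]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise SuitabilityError(
            f"suitability values outside [0,1]: range [{vals.min()}, {vals.max()}]"
        )
    # np.digitize with right=False puts x == cut into the upper bin
    out = np.zeros(suit.shape, dtype=float)
    out[valid] = np.digitize(suit.values[valid], list(classes.cuts), right=False)
    return GridLayer(out, suit.cellsize, suit.origin, suit.nodata_mask.copy(),
                     suit.crs_tag, "categorical")


def area_table(classified: GridLayer, cellsize: float | None = None,
               scenario: str = "") -> AreaTable:
    """Class areas: count × cellsize² / 10⁶ km² per class."""
    if classified.kind != "categorical":
        raise SuitabilityError("area_table expects a classified (categorical) layer")
    cs = classified.cellsize if cellsize is None else cellsize
    valid = classified.valid_mask
    codes, counts = np.unique(classified.values[valid].astype(int), return_counts=True)
    unknown = set(codes.tolist()) - set(CLASS_LABELS)
    if unknown:
        raise SuitabilityError(f"unknown class labels on the map: {sorted(unknown)}")
    cell_km2 = cs * cs / 1e6
    areas = {int(c): float(n) * cell_km2 for c, n in zip(codes, counts)}
    for c in CLASS_LABELS:
        areas.setdefault(c, 0.0)
    return AreaTable(areas, scenario)


def area_table_from_counts(areas_km2: Dict[int, float], scenario: str = "") -> AreaTable:
    """Build an AreaTable directly from per-class km² figures."""
    return AreaTable(dict(areas_km2), scenario)


def scenario_delta(a: AreaTable, b: AreaTable) -> Tuple[float, float]:
    """(absolute change km², percent decrease to 2 decimals) from a to b.

    ``abs_change`` is signed ``total(b) − total(a)``; ``pct_change`` is the
    decrease ``100·(total(a) − total(b))/total(a)`` (positive = loss).
    """
    ta, tb = a.total_suitable_km2, b.total_suitable_km2
    if ta <= 0:
        raise SuitabilityError("baseline table has zero suitable area")
    abs_change = tb - ta
    pct_change = round_half_away(100.0 * (ta - tb) / ta, 2)
    return abs_change, pct_change


def centroid(
    suit: GridLayer,
    classified: GridLayer,
    dem: Optional[GridLayer] = None,
    binary: bool = False,
) -> HabitatCentroid:
    """Suitability-weighted centre of mass over suitable cells (class >= 1).

    With ``binary=True`` every suitable cell weighs 1. ``mean_elevation``
    is the same weighted mean over the DEM when one is supplied.
    """
    suitable = classified.valid_mask & (classified.values >= 1)
    if not suitable.any():
        raise SuitabilityError("no suitable cells; centroid undefined")
    xs, ys = suit.cell_centers()
    w = np.ones(suit.shape) if binary else suit.values
    w = np.where(suitable, w, 0.0)
    wsum = w.sum()
    if wsum <= 0:
        raise SuitabilityError("zero total weight over suitable cells")
    cx = float((w * xs).sum() / wsum)
    cy = float((w * ys).sum() / wsum)
    elev = None
    if dem is not None:
        elev = float((w * dem.values).sum() / wsum)
    return HabitatCentroid(cx, cy, elev)


def centroid_shift(c1: HabitatCentroid, c2: HabitatCentroid) -> Tuple[float, float, float]:
    """(distance m, compass bearing °, elevation change m) from c1 to c2.

    Bearing is clockwise from north; NaN when the displacement is zero.
    """
    dx = c2.x - c1.x
    dy = c2.y - c1.y
    dist = math.hypot(dx, dy)
    bearing = math.degrees(math.atan2(dx, dy)) % 360.0 if dist > 0 else float("nan")
    if c1.mean_elevation is None or c2.mean_elevation is None:
        delev = float("nan")
    else:
        delev = c2.mean_elevation - c1.mean_elevation
    return dist, bearing, delev
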