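"""Resistance surfaces and minimum-cumulative-resistance corridors.

Each environmental factor is binned into five resistance levels
{10, 20, 30, 40, 50} — either from a packaged scheme table or derived
from a fitted model's marginal response (top suitability quintile → 10,
bottom → 50). Factor surfaces are blended with weights normalized to sum
to one, so the surface is invariant to uniform weight rescaling.

Accumulated cost is computed by Dijkstra over the 8-connected lattice with
average-resistance step costs ``d(a,b) · (R_a + R_b) / 2`` (d = cellsize,
or √2·cellsize diagonally), the standard discretization of a
distance-times-resistance line integral. Corridors are backlink traces
from the cheapest cell of the destination patch.
"""

from __future__ import annotations

import csv
import heapq
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import EnvStack, GridLayer
from .maxent import MaxEntModel, response_curve

__all__ = [
    "ResistanceScheme",
    "SourcePatch",
    "CostDistanceField",
    "CorridorSet",
    "scheme_from_response",
    "load_scheme",
    "resistance_surface",
    "identify_sources",
    "cost_distance",
    "least_cost_corridors",
]

RESISTANCE_LEVELS = (10, 20, 30, 40, 50)


class CorridorError(ValueError):
    pass


@dataclass
class FactorBins:
    """Value→resistance mapping for one factor.

    Continuous factors use half-open numeric bins ``(lo, hi] → level``
    (the bin holding the factor's observed minimum is closed below);
    categorical factors map explicit code sets.
    """

    intervals: List[Tuple[float, float, int]] = field(default_factory=list)
    categories: Dict[int, int] = field(default_factory=dict)
    # categories named by label rather than raster code (e.g. land-cover
    # legends); mapped to codes via a legend before rasters can be scored
    category_labels: Dict[str, int] = field(default_factory=dict)

    @property
    def is_categorical(self) -> bool:
        return bool(self.categories) or bool(self.category_labels)

    def with_legend(self, legend: Dict[str, int]) -> "FactorBins":
        """Resolve labelled categories to integer codes via ``legend``."""
        codes = dict(self.categories)
        for label, level in self.category_labels.items():
            if label not in legend:
                raise CorridorError(f"legend lacks land-cover label {label!r}")
            codes[int(legend[label])] = level
        return FactorBins(list(self.intervals), codes, {})

    def resistance_of(self, values: np.ndarray, factor: str) -> np.ndarray:
        out = np.full(values.shape, np.nan)
        if self.is_categorical:
            for code, level in self.categories.items():
                out[values == code] = level
        else:
            lo_all = min(lo for lo, _, _ in self.intervals)
            for lo, hi, level in self.intervals:
                if lo == lo_all:
                    sel = (values >= lo) & (values <= hi)
                else:
                    sel = (values > lo) & (values <= hi)
                out[sel] = level
        if np.isnan(out).any():
            bad = values[np.isnan(out)]
            raise CorridorError(
                f"factor {factor!r}: value {bad.flat[0]!r} falls in no resistance bin"
            )
        return out


@dataclass
class ResistanceScheme:
    """Per-factor resistance bins plus per-factor weights."""

    factors: Dict[str, FactorBins]
    weights: Dict[str, float]

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if w < 0:
                raise CorridorError(f"negative weight for factor {name!r}")
            if name not in self.factors:
                raise CorridorError(f"weight given for unknown factor {name!r}")

    def normalized_weights(self) -> Dict[str, float]:
        total = sum(self.weights.values())
        if total <= 0:
            raise CorridorError("scheme weights sum to zero")
        return {k: v / total for k, v in self.weights.items()}


def load_scheme(path: str) -> ResistanceScheme:
    """Read a scheme CSV: factor, kind, r10..r50, weight.

    Continuous cells hold ``lo..hi`` ranges (``;``-separated for
    non-contiguous sets); categorical cells hold ``;``-separated codes.
    """
    factors: Dict[str, FactorBins] = {}
    weights: Dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"factor", "kind", "weight"} | {f"r{v}" for v in RESISTANCE_LEVELS}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise CorridorError(f"{path}: scheme CSV must have columns {sorted(need)}")
        for row in reader:
            name = row["factor"].strip()
            # tolerate legacy truncated variable names like "Bo7"
            if name.startswith("Bo") and name[2:].isdigit():
                name = "Bio" + name[2:]
            bins = FactorBins()
            for level in RESISTANCE_LEVELS:
                cell = (row.get(f"r{level}") or "").strip()
                if not cell:
                    continue
                for part in cell.split(";"):
                    part = part.strip()
                    if not part:
                        continue
                    if row["kind"].strip() == "categorical":
                        try:
                            bins.categories[int(float(part))] = level
                        except ValueError:
                            bins.category_labels[part] = level
                    else:
                        lo_s, hi_s = part.split("..")
                        bins.intervals.append((float(lo_s), float(hi_s), level))
            factors[name] = bins
            weights[name] = float(row["weight"])
    return ResistanceScheme(factors, weights)


def write_scheme(scheme: ResistanceScheme, path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["factor", "kind"] + [f"r{v}" for v in RESISTANCE_LEVELS]
                        + ["weight"])
        for name, bins in scheme.factors.items():
            cells = {v: [] for v in RESISTANCE_LEVELS}
            kind = "categorical" if bins.is_categorical else "continuous"
            if bins.is_categorical:
                for code, level in bins.categories.items():
                    cells[level].append(str(code))
            else:
                for lo, hi, level in bins.intervals:
                    cells[level].append(f"{lo!r}..{hi!r}")
            writer.writerow([name, kind] + [";".join(cells[v]) for v in RESISTANCE_LEVELS]
                            + [repr(scheme.weights[name])])


def scheme_from_response(
    model: MaxEntModel,
    stack: EnvStack,
    contributions: Dict[str, float],
    n_levels: int = 5,
    n_points: int = 100,
) -> ResistanceScheme:
    """Derive bins from the model's marginal responses, weights from
    contributions.

    Each factor's response is sampled on a grid; points are ranked into
    suitability quintiles (top quintile → resistance 10, bottom → 50) and
    consecutive equal-level points merge into intervals. A flat response
    collapses to a single all-range level-30 bin with a warning.
    """
    if n_levels != len(RESISTANCE_LEVELS):
        raise CorridorError("only the standard 5-level scheme is supported")
    factors: Dict[str, FactorBins] = {}
    for var in model.source_variables:
        curve = response_curve(model, stack, var, n_points=n_points)
        values = np.array([v for v, _ in curve])
        suits = np.array([s for _, s in curve])
        bins = FactorBins()
        categorical = model.variable_kinds.get(var) == "categorical"
        if float(suits.max() - suits.min()) < 1e-12:
            warnings.warn(f"factor {var!r}: flat response; assigning level 30 everywhere")
            if categorical:
                bins.categories = {int(v): 30 for v in values}
            else:
                bins.intervals = [(float(values.min()), float(values.max()), 30)]
            factors[var] = bins
            continue
        # suitability quantile of each sampled point -> resistance level
        qs = np.quantile(suits, [0.2, 0.4, 0.6, 0.8])
        quint = np.digitize(suits, qs, right=True)  # 0 (worst) .. 4 (best)
        levels = np.array(RESISTANCE_LEVELS)[::-1][quint]  # best -> 10
        if categorical:
            bins.categories = {int(v): int(l) for v, l in zip(values, levels)}
        else:
            # merge consecutive runs of the same level into intervals
            edges = np.concatenate([[values[0]],
                                    (values[1:] + values[:-1]) / 2.0,
                                    [values[-1]]])
            start = 0
            for i in range(1, len(values) + 1):
                if i == len(values) or levels[i] != levels[start]:
                    bins.intervals.append(
                        (float(edges[start]), float(edges[i]), int(levels[start]))
                    )
                    start = i
        factors[var] = bins
    weights = {v: float(contributions.get(v, 0.0)) for v in factors}
    return ResistanceScheme(factors, weights)


def resistance_surface(stack: EnvStack, scheme: ResistanceScheme) -> GridLayer:
    """Weighted overlay ``R(x) = Σ_f w_f · r_f(x)`` with Σ w_f = 1."""
    missing = [f for f in scheme.factors if f not in stack]
    if missing:
        raise CorridorError(f"stack is missing scheme factor(s): {missing}")
    weights = scheme.normalized_weights()
    mask = stack.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    acc = np.zeros(rows.shape)
    for name, bins in scheme.factors.items():
        vals = stack[name].values[rows, cols]
        acc += weights[name] * bins.resistance_of(vals, name)
    template = stack.template
    out = np.zeros(template.shape)
    out[rows, cols] = acc
    return GridLayer(out, template.cellsize, template.origin, ~mask,
                     template.crs_tag, "continuous")


# ---------------------------------------------------------------------------
# Sources
# ---------------------------------------------------------------------------

@dataclass
class SourcePatch:
    id: int
    cells: np.ndarray  # (n, 2) row/col indices
    area_km2: float
    centroid: Tuple[float, float]


def identify_sources(
    classified: GridLayer, min_area_km2: float = 10.0, cellsize: float | None = None
) -> List[SourcePatch]:
    """8-connected components of the top class (3) above an area threshold."""
    if classified.kind != "categorical":
        raise CorridorError("identify_sources expects a classified layer")
    cs = classified.cellsize if cellsize is None else cellsize
    top = classified.valid_mask & (classified.values == 3)
    labels, n = ndimage.label(top, structure=np.ones((3, 3), int))
    cell_km2 = cs * cs / 1e6
    patches: List[SourcePatch] = []
    pid = 0
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        area = rr.size * cell_km2
        if area < min_area_km2:
            continue
        xs = np.array([classified.cell_center(r, c) for r, c in zip(rr, cc)])
        pid += 1
        patches.append(SourcePatch(pid, np.column_stack([rr, cc]), area,
                                   (float(xs[:, 0].mean()), float(xs[:, 1].mean()))))
    if not patches:
        warnings.warn("no source patches above the area threshold")
    return patches


# ---------------------------------------------------------------------------
# Cost distance (MCR)
# ---------------------------------------------------------------------------

# 8-way neighbour offsets; backlink code i points to _OFFSETS[i] predecessor
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CostDistanceField:
    accumulated_cost: GridLayer
    backlink: np.ndarray  # int8, -1 = none/source
    source_id: int


def cost_distance(
    resistance: GridLayer,
    source_cells: np.ndarray,
    source_id: int = 0,
    connectivity: int = 8,
) -> CostDistanceField:
    """Dijkstra accumulation of ``d · (R_a + R_b)/2`` from a source patch.

    ``source_cells`` is an ``(n, 2)`` row/col array. Masked cells are
    impassable; unreachable cells stay at +inf.
    """
    R = resistance.values
    valid = resistance.valid_mask
    if np.any(R[valid] <= 0):
        raise CorridorError("resistance must be strictly positive on valid cells")
    if connectivity not in (4, 8):
        raise CorridorError("connectivity must be 4 or 8")
    offsets = _OFFSETS if connectivity == 8 else [o for o in _OFFSETS if 0 in o]
    nrows, ncols = R.shape
    cs = resistance.cellsize
    cost = np.full(R.shape, np.inf)
    backlink = np.full(R.shape, -1, dtype=np.int8)
    heap: List[Tuple[float, int, int]] = []
    src = np.asarray(source_cells, dtype=int)
    if src.size == 0:
        raise CorridorError("empty source patch")
    for r, c in src:
        if not valid[r, c]:
            continue
        cost[r, c] = 0.0
        heapq.heappush(heap, (0.0, int(r), int(c)))
    if not heap:
        raise CorridorError("source patch lies entirely on masked cells")
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > cost[r, c]:
            continue
        for code, (dr, dc) in enumerate(offsets):
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrows and 0 <= nc < ncols) or not valid[nr, nc]:
                continue
            step = cs * (math.sqrt(2.0) if dr and dc else 1.0)
            nd = d + step * (R[r, c] + R[nr, nc]) / 2.0
            if nd < cost[nr, nc]:
                cost[nr, nc] = nd
                # backlink points back towards the source
                backlink[nr, nc] = _OFFSETS.index((-dr, -dc))
                heapq.heappush(heap, (nd, nr, nc))
    layer = GridLayer(np.where(np.isfinite(cost), cost, 0.0), cs, resistance.origin,
                      ~(valid & np.isfinite(cost)), resistance.crs_tag, "continuous")
    layer.values[~np.isfinite(cost) & valid] = np.inf
    return CostDistanceField(layer, backlink, source_id)


# ---------------------------------------------------------------------------
# Corridors
# ---------------------------------------------------------------------------

@dataclass
class Corridor:
    source_a: int
    source_b: int
    path_cells: List[Tuple[int, int]]
    polyline: List[Tuple[float, float]]
    total_cost: float
    connected: bool = True


@dataclass
class CorridorSet:
    corridors: List[Corridor]
    sources: List[SourcePatch]

    def to_geojson(self, path: str) -> None:
        features = []
        for c in self.corridors:
            if not c.connected:
                continue
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [[x, y] for x, y in c.polyline]},
                "properties": {"source_a": c.source_a, "source_b": c.source_b,
                               "total_cost": c.total_cost},
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _trace(field: CostDistanceField, start: Tuple[int, int]) -> List[Tuple[int, int]]:
    path = [start]
    r, c = start
    bl = field.backlink
    guard = bl.size + 1
    while bl[r, c] >= 0 and guard:
        dr, dc = _OFFSETS[bl[r, c]]
        r, c = r + dr, c + dc
        path.append((r, c))
        guard -= 1
    return path


def least_cost_corridors(
    resistance: GridLayer,
    sources: Sequence[SourcePatch],
    connectivity: int = 8,
) -> CorridorSet:
    """Least-cost path between every unordered pair of source patches.

    Patch-to-patch cost uses nearest-member semantics (minimum over the
    destination patch of the source patch's cost field). Pairs severed by
    the mask are flagged disconnected rather than erroring.
    """
    if len(sources) < 2:
        raise CorridorError("need at least two source patches")
    fields = {p.id: cost_distance(resistance, p.cells, p.id, connectivity)
              for p in sources}
    corridors: List[Corridor] = []
    for i, a in enumerate(sources):
        for b in sources[i + 1 :]:
            fa = fields[a.id]
            costs_at_b = np.array([fa.accumulated_cost.values[r, c] for r, c in b.cells])
            j = int(np.argmin(costs_at_b))
            total = float(costs_at_b[j])
            if not np.isfinite(total):
                corridors.append(Corridor(a.id, b.id, [], [], math.inf, connected=False))
                continue
            cells = _trace(fa, (int(b.cells[j, 0]), int(b.cells[j, 1])))
            poly = [resistance.cell_center(r, c) for r, c in cells]
            corridors.append(Corridor(a.id, b.id, cells, poly, total))
    return CorridorSet(corridors, list(sources))
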