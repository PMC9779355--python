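"""Raster data model, I/O, alignment, and derived terrain/distance layers.

The :class:`GridLayer` is the universal currency of the pipeline: a single
band of square cells in a projected CRS, row 0 being the northernmost row.
Cell centre of cell ``(r, c)`` is
``(x_min + (c + 0.5) * cellsize, y_max - (r + 0.5) * cellsize)``.

Two interchange formats are supported: ESRI ASCII grid (plain text, written
with 6 significant digits) and single-band GeoTIFF (via :mod:`tifffile`,
carrying ``ModelPixelScale``/``ModelTiepoint`` tags and a GDAL nodata tag).

Distances produced by :func:`distance_to_class` are centre-to-centre
Euclidean distances, the conventional way distance rasters are derived from
classified land cover.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "GridLayer",
    "EnvStack",
    "read_grid",
    "write_grid",
    "align_stack",
    "resample_layer",
    "slope_aspect",
    "distance_to_class",
]

_NODATA_DEFAULT = -9999.0

# GeoTIFF / GDAL private tags used for georeferencing round-trips.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridError(ValueError):
    """Raised for malformed rasters or inconsistent grid geometry."""


@dataclass
class GridLayer:
    """One georeferenced raster band with a nodata mask.

    Parameters
    ----------
    values
        2-D float array; row 0 is the northernmost row. Values under the
        mask are unspecified and must never be consumed.
    cellsize
        Positive square cell size in metres.
    origin
        ``(x_min, y_max)`` of the top-left *corner* of the grid.
    nodata_mask
        Boolean array, ``True`` where the cell carries no data.
    crs_tag
        Opaque CRS identifier carried through I/O; never interpreted.
    kind
        ``"continuous"`` or ``"categorical"``. Categorical layers hold
        integer codes outside the mask.
    """

    values: np.ndarray
    cellsize: float
    origin: Tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    crs_tag: str = ""
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridError("GridLayer values must be a 2-D array")
        if self.cellsize <= 0:
            raise GridError("cellsize must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise GridError("values and nodata_mask must share a shape")
        if self.kind not in ("continuous", "categorical"):
            raise GridError(f"unknown layer kind {self.kind!r}")
        if self.kind == "categorical":
            valid = self.values[~self.nodata_mask]
            if valid.size and not np.allclose(valid, np.round(valid)):
                raise GridError("categorical layer holds non-integer codes")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` arrays of cell-centre coordinates."""
        rows, cols = self.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(cols) + 0.5) * self.cellsize
        y = y0 - (np.arange(rows) + 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def cell_center(self, row: int, col: int) -> Tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cellsize, y0 - (row + 0.5) * self.cellsize)

    def index_of(self, x: float, y: float) -> Tuple[int, int]:
        """Row/col of the cell containing the point ``(x, y)``."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cellsize))
        row = int(math.floor((y0 - y) / self.cellsize))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        r, c = self.index_of(x, y)
        return 0 <= r < self.shape[0] and 0 <= c < self.shape[1]

    def same_geometry(self, other: "GridLayer", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cellsize, other.cellsize, rel_tol=rtol)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=rtol, abs_tol=1e-6)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=rtol, abs_tol=1e-6)
        )

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.nodata_mask)

    def copy(self, **changes) -> "GridLayer":
        base = replace(self)
        base.values = self.values.copy()
        base.nodata_mask = self.nodata_mask.copy()
        for k, v in changes.items():
            setattr(base, k, v)
        return base


@dataclass
class EnvStack:
    """Named, grid-aligned collection of predictor layers.

    All layers share shape, cellsize, origin and CRS tag. At most one layer
    per name is categorical; a layer named ``"LUCC"`` must be categorical.
    Model operations use the joint valid mask (intersection of the per-layer
    valid masks).
    """

    layers: Dict[str, GridLayer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ref = None
        for name, layer in self.layers.items():
            if ref is None:
                ref = layer
            elif not layer.same_geometry(ref):
                raise GridError(f"layer {name!r} is not aligned with the stack")
            if name == "LUCC" and layer.kind != "categorical":
                raise GridError("LUCC layer must be categorical")

    def __getitem__(self, name: str) -> GridLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self):
        return iter(self.layers)

    @property
    def names(self) -> List[str]:
        return list(self.layers)

    @property
    def template(self) -> GridLayer:
        return next(iter(self.layers.values()))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.template.shape

    @property
    def cellsize(self) -> float:
        return self.template.cellsize

    def joint_valid_mask(self) -> np.ndarray:
        mask = np.ones(self.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.valid_mask
        return mask

    def continuous_names(self) -> List[str]:
        return [n for n, l in self.layers.items() if l.kind == "continuous"]

    def categorical_names(self) -> List[str]:
        return [n for n, l in self.layers.items() if l.kind == "categorical"]

    def subset(self, names: Iterable[str]) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names})

    def with_layer(self, name: str, layer: GridLayer) -> "EnvStack":
        new = dict(self.layers)
        new[name] = layer
        return EnvStack(new)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_ascii_grid(path: str, kind: str) -> GridLayer:
    header: Dict[str, float] = {}
    rows: List[List[float]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                   "yllcenter", "cellsize", "dx", "dy", "nodata_value"}
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for line in lines[i:]:
        if line.strip():
            rows.append([float(v) for v in line.split()])
    for key in ("ncols", "nrows", "cellsize"):
        if "dx" in header and key == "cellsize":
            continue
        if key not in header:
            raise GridError(f"{path}: ASCII grid missing {key!r} header")
    if "dx" in header or "dy" in header:
        dx, dy = header.get("dx"), header.get("dy")
        if dx != dy:
            raise GridError(f"{path}: non-square cells (dx={dx}, dy={dy})")
        header["cellsize"] = float(dx)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = float(header["cellsize"])
    values = np.array(rows, dtype=float)
    if values.shape != (nrows, ncols):
        raise GridError(
            f"{path}: grid body is {values.shape}, header says ({nrows}, {ncols})"
        )
    if "nodata_value" not in header:
        raise GridError(f"{path}: ASCII grid lacks a NODATA_value declaration")
    nodata = header["nodata_value"]
    mask = values == nodata
    if "xllcorner" in header:
        x_min = header["xllcorner"]
        y_min = header["yllcorner"]
    elif "xllcenter" in header:
        x_min = header["xllcenter"] - cellsize / 2
        y_min = header["yllcenter"] - cellsize / 2
    else:
        x_min = y_min = 0.0
    origin = (x_min, y_min + nrows * cellsize)
    return GridLayer(values, cellsize, origin, mask, crs_tag="", kind=kind)


def _read_geotiff(path: str, kind: str) -> GridLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise GridError(f"{path}: expected a single-band raster")
        tags = page.tags
        scale = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise GridError(f"{path}: GeoTIFF lacks georeferencing tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise GridError(f"{path}: non-square cells ({sx} x {sy})")
        # tiepoint maps raster (i, j, k) -> model (x, y, z); we anchor (0, 0).
        tp = tiepoint.value
        origin = (float(tp[3]) - float(tp[0]) * sx, float(tp[4]) + float(tp[1]) * sy)
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        mask = np.zeros(values.shape, dtype=bool)
        if nodata_tag is not None:
            nodata = float(nodata_tag.value)
            mask = (values == nodata) | ~np.isfinite(values)
        else:
            mask = ~np.isfinite(values)
        crs_tag = ""
        desc = page.description or ""
        if desc:
            try:
                meta = json.loads(desc)
                crs_tag = meta.get("crs_tag", "")
                kind = meta.get("kind", kind)
            except (json.JSONDecodeError, AttributeError):
                pass
    return GridLayer(values, sx, origin, mask, crs_tag=crs_tag, kind=kind)


def read_grid(path: str, kind: str = "continuous") -> GridLayer:
    """Read a GeoTIFF or ESRI ASCII grid into a :class:`GridLayer`.

    The format is sniffed from the file contents, not the extension. ASCII
    grids must declare ``NODATA_value`` explicitly and have square cells.
    """
    if not os.path.exists(path):
        raise GridError(f"raster file not found: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] in (b"II", b"MM"):
        return _read_geotiff(path, kind)
    return _read_ascii_grid(path, kind)


def write_grid(layer: GridLayer, path: str, fmt: str | None = None) -> None:
    """Write a layer as ESRI ASCII (``.asc``/``.txt``) or GeoTIFF (default).

    ASCII output uses 6 significant digits and the ``-9999`` nodata
    convention (categorical layers are written as integers).
    """
    if fmt is None:
        fmt = "ascii" if os.path.splitext(path)[1].lower() in (".asc", ".txt") else "gtiff"
    if fmt == "ascii":
        nrows, ncols = layer.shape
        x_min, y_max = layer.origin
        y_min = y_max - nrows * layer.cellsize
        out = layer.values.copy()
        out[layer.nodata_mask] = _NODATA_DEFAULT
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {x_min!r}\n")
            fh.write(f"yllcorner {y_min!r}\n")
            fh.write(f"cellsize {layer.cellsize!r}\n")
            fh.write(f"NODATA_value {int(_NODATA_DEFAULT)}\n")
            if layer.kind == "categorical":
                fmtcell = "{:d}".format
                body = "\n".join(
                    " ".join(fmtcell(int(round(v))) for v in row) for row in out
                )
            else:
                body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in out)
            fh.write(body + "\n")
    elif fmt == "gtiff":
        import tifffile

        out = layer.values.astype(np.float64).copy()
        out[layer.nodata_mask] = _NODATA_DEFAULT
        x_min, y_max = layer.origin
        desc = json.dumps({"crs_tag": layer.crs_tag, "kind": layer.kind})
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (layer.cellsize, layer.cellsize, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x_min, y_max, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(int(_NODATA_DEFAULT))),
        ]
        tifffile.imwrite(path, out, description=desc, extratags=extratags)
    else:
        raise GridError(f"unknown raster format {fmt!r}")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def resample_layer(layer: GridLayer, target: GridLayer, resampling: str) -> GridLayer:
    """Resample a single layer onto ``target``'s geometry.

    Bilinear resampling of a categorical layer is refused: interpolating
    class codes fabricates classes.
    """
    if layer.kind == "categorical" and resampling == "bilinear":
        raise GridError("bilinear resampling is invalid for a categorical layer")
    return _resample(layer, target, resampling)


def _resample(layer: GridLayer, target: GridLayer, resampling: str) -> GridLayer:
    """Resample `layer` onto `target`'s geometry (nearest or bilinear)."""
    tx, ty = target.cell_centers()
    # fractional source pixel coordinates of target cell centres
    sx0, sy0 = layer.origin
    col_f = (tx - sx0) / layer.cellsize - 0.5
    row_f = (sy0 - ty) / layer.cellsize - 0.5
    nrows, ncols = layer.shape
    if resampling == "nearest":
        r = np.clip(np.round(row_f).astype(int), 0, nrows - 1)
        c = np.clip(np.round(col_f).astype(int), 0, ncols - 1)
        values = layer.values[r, c]
        mask = layer.nodata_mask[r, c]
    elif resampling == "bilinear":
        vals = layer.values.astype(float).copy()
        vals[layer.nodata_mask] = np.nan
        r0 = np.clip(np.floor(row_f).astype(int), 0, nrows - 1)
        c0 = np.clip(np.floor(col_f).astype(int), 0, ncols - 1)
        r1 = np.clip(r0 + 1, 0, nrows - 1)
        c1 = np.clip(c0 + 1, 0, ncols - 1)
        fr = np.clip(row_f - r0, 0.0, 1.0)
        fc = np.clip(col_f - c0, 0.0, 1.0)
        v00, v01 = vals[r0, c0], vals[r0, c1]
        v10, v11 = vals[r1, c0], vals[r1, c1]
        values = (
            v00 * (1 - fr) * (1 - fc)
            + v01 * (1 - fr) * fc
            + v10 * fr * (1 - fc)
            + v11 * fr * fc
        )
        mask = ~np.isfinite(values)
        values = np.where(mask, 0.0, values)
    else:
        raise GridError(f"unknown resampling {resampling!r}")
    # target cells outside the source extent have no data
    outside = (col_f < -0.5) | (col_f > ncols - 0.5) | (row_f < -0.5) | (row_f > nrows - 0.5)
    mask = mask | outside
    return GridLayer(values, target.cellsize, target.origin, mask,
                     crs_tag=target.crs_tag or layer.crs_tag, kind=layer.kind)


def align_stack(
    layers: Mapping[str, GridLayer] | Sequence[Tuple[str, GridLayer]],
    target: GridLayer,
    resampling: str = "bilinear",
) -> EnvStack:
    """Resample named layers onto ``target``'s geometry into an EnvStack.

    Categorical layers are always resampled nearest-neighbour; requesting
    bilinear for a categorical layer explicitly (by passing
    ``resampling='bilinear'`` when *all* layers are categorical) is refused
    per-layer, silently falling back is not done.
    """
    items = layers.items() if isinstance(layers, Mapping) else list(layers)
    out: Dict[str, GridLayer] = {}
    for name, layer in items:
        x_min, y_max = layer.origin
        x_max = x_min + layer.shape[1] * layer.cellsize
        y_min = y_max - layer.shape[0] * layer.cellsize
        t_xmin, t_ymax = target.origin
        t_xmax = t_xmin + target.shape[1] * target.cellsize
        t_ymin = t_ymax - target.shape[0] * target.cellsize
        if x_max <= t_xmin or x_min >= t_xmax or y_max <= t_ymin or y_min >= t_ymax:
            raise GridError(f"layer {name!r} does not overlap the target extent")
        if layer.same_geometry(target):
            out[name] = layer
            continue
        method = "nearest" if layer.kind == "categorical" else resampling
        out[name] = _resample(layer, target, method)
    return EnvStack(out)


# ---------------------------------------------------------------------------
# Derived layers
# ---------------------------------------------------------------------------

def slope_aspect(dem: GridLayer) -> Tuple[GridLayer, GridLayer]:
    """Slope and aspect (degrees) from a DEM by Horn's 3x3 method.

    Slope is ``arctan(|grad z|)``. Aspect is the compass direction the cell
    *faces downhill*, clockwise from north in ``[0, 360)``; a plane dipping
    towards the east (z increasing westwards) has aspect 90. Flat cells get
    the sentinel ``-1``. Border cells and cells whose 3x3 window touches
    nodata are masked.
    """
    if dem.kind != "continuous":
        raise GridError("slope_aspect requires a continuous DEM")
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise GridError("DEM must be at least 3x3")
    if not dem.valid_mask.any():
        raise GridError("DEM is entirely masked")
    z = dem.values
    cs = dem.cellsize
    nrows, ncols = dem.shape

    # Horn kernel on the interior
    zp = np.pad(z, 1, mode="edge")

    def sh(dr: int, dc: int) -> np.ndarray:
        return zp[1 + dr : 1 + dr + nrows, 1 + dc : 1 + dc + ncols]

    # dz/dx positive eastwards, dz/dy positive northwards
    dzdx = ((sh(-1, 1) + 2 * sh(0, 1) + sh(1, 1))
            - (sh(-1, -1) + 2 * sh(0, -1) + sh(1, -1))) / (8 * cs)
    dzdy = ((sh(-1, -1) + 2 * sh(-1, 0) + sh(-1, 1))
            - (sh(1, -1) + 2 * sh(1, 0) + sh(1, 1))) / (8 * cs)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downhill direction is -grad; atan2(east, north) measured from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.where(flat, -1.0, aspect)

    mask = np.zeros(dem.shape, dtype=bool)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = True
    bad = ndimage.binary_dilation(dem.nodata_mask, structure=np.ones((3, 3), bool))
    mask |= bad
    slope_layer = GridLayer(slope, cs, dem.origin, mask, dem.crs_tag, "continuous")
    aspect_layer = GridLayer(aspect, cs, dem.origin, mask.copy(), dem.crs_tag, "continuous")
    return slope_layer, aspect_layer


def distance_to_class(source: GridLayer, codes: Iterable[int]) -> GridLayer:
    """Euclidean distance (metres, centre-to-centre) to the nearest cell
    whose categorical code is in ``codes``. Source cells map to 0."""
    if source.kind != "categorical":
        raise GridError("distance_to_class requires a categorical layer")
    codes = set(int(c) for c in codes)
    is_source = np.zeros(source.shape, dtype=bool)
    valid = source.valid_mask
    vals = np.where(valid, source.values, np.nan)
    for code in codes:
        is_source |= valid & (vals == code)
    if not is_source.any():
        raise GridError(f"no cells carry any of the requested codes {sorted(codes)}")
    dist = ndimage.distance_transform_edt(~is_source, sampling=source.cellsize)
    return GridLayer(dist, source.cellsize, source.origin,
                     source.nodata_mask.copy(), source.crs_tag, "continuous")
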