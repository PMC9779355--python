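"""Synthetic landscapes with known response structure.

Generates aligned raster stacks (smoothed seeded noise for the bioclimate
layers, a smooth DEM, a thresholded categorical land-cover layer and
derived distance layers) plus presence samples drawn from a known logistic
suitability, so every pipeline stage can be exercised end to end without
external data.

Smoothing is a truncated moving-average kernel; the ``smoothness``
parameter is the kernel radius in cells. All randomness flows from a
single spec seed through named substreams, so the draw of one product
never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .grids import EnvStack, GridLayer, distance_to_class
from .occurrences import OccurrenceSet

__all__ = ["SyntheticSpec", "make_landscape", "sample_presences",
           "WATER_CODE", "GRASSLAND_CODE"]

WATER_CODE = 1
GRASSLAND_CODE = 2


class SyntheticError(ValueError):
    pass


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SyntheticSpec:
    shape: Tuple[int, int] = (80, 80)
    cellsize: float = 1000.0
    n_continuous: int = 3
    smoothness: int = 4          # moving-average kernel radius, cells
    lucc_classes: int = 4
    true_response: Dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    n_presences: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 3 or self.shape[1] < 3:
            raise SyntheticError("degenerate landscape shape")
        if self.n_continuous < 1:
            raise SyntheticError("need at least one continuous layer")
        if self.lucc_classes < 2:
            raise SyntheticError("need at least two land-cover classes")


def _smooth_field(rng: np.random.Generator, shape: Tuple[int, int],
                  radius: int) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if radius > 0:
        noise = ndimage.uniform_filter(noise, size=2 * radius + 1, mode="reflect")
    sd = noise.std()
    return (noise - noise.mean()) / (sd if sd > 0 else 1.0)


def make_landscape(spec: SyntheticSpec) -> EnvStack:
    """Build the aligned synthetic stack: Bio1..BioK, DEM, LUCC, DW, DH."""
    rows, cols = spec.shape
    layers: Dict[str, GridLayer] = {}

    def grid(values: np.ndarray, kind: str = "continuous") -> GridLayer:
        return GridLayer(values, spec.cellsize, (0.0, rows * spec.cellsize),
                         np.zeros(spec.shape, dtype=bool), "synthetic", kind)

    for i in range(spec.n_continuous):
        name = f"Bio{i + 1}"
        f = _smooth_field(_substream(spec.seed, f"landscape/{name}"),
                          spec.shape, spec.smoothness)
        # rescale standardized field to a plausible climate-like range
        lo, hi = 10.0 * (i + 1), 10.0 * (i + 1) + 50.0
        v = np.interp(f, (f.min(), f.max()), (lo, hi))
        layers[name] = grid(v)

    dem_field = _smooth_field(_substream(spec.seed, "landscape/DEM"),
                              spec.shape, max(spec.smoothness, 3))
    dem = np.interp(dem_field, (dem_field.min(), dem_field.max()), (3000.0, 5000.0))
    layers["DEM"] = grid(dem)

    lucc_field = _smooth_field(_substream(spec.seed, "landscape/LUCC"),
                               spec.shape, max(spec.smoothness, 1))
    qs = np.quantile(lucc_field, np.linspace(0, 1, spec.lucc_classes + 1)[1:-1])
    lucc = np.digitize(lucc_field, qs) + 1  # codes 1..k
    layers["LUCC"] = grid(lucc.astype(float), "categorical")

    layers["DW"] = distance_to_class(layers["LUCC"], {WATER_CODE})
    layers["DH"] = distance_to_class(layers["LUCC"], {GRASSLAND_CODE})
    return EnvStack(layers)


def true_suitability(stack: EnvStack, true_response: Dict[str, float],
                     intercept: float = 0.0) -> np.ndarray:
    """Logistic ground-truth suitability over the grid from standardized
    continuous variables."""
    missing = [v for v in true_response if v not in stack]
    if missing:
        raise SyntheticError(f"response variables not in stack: {missing}")
    eta = np.full(stack.shape, float(intercept))
    for var, coef in true_response.items():
        vals = stack[var].values
        sd = vals.std()
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        eta = eta + coef * z
    from scipy.special import expit

    return expit(eta)


def sample_presences(
    stack: EnvStack,
    true_response: Dict[str, float],
    n: int,
    seed: int,
    intercept: float = 0.0,
) -> OccurrenceSet:
    """Draw presence cells with probability proportional to the true
    suitability; points land on cell centres."""
    if n < 0:
        raise SyntheticError("n must be non-negative")
    if n == 0:
        return OccurrenceSet([], "synthetic")
    suit = true_suitability(stack, true_response, intercept)
    mask = stack.joint_valid_mask()
    rows, cols = np.nonzero(mask)
    weights = suit[rows, cols]
    total = weights.sum()
    if total <= 0:
        raise SyntheticError("total true suitability is zero; cannot sample")
    rng = _substream(seed, "presences")
    idx = rng.choice(rows.size, size=n, replace=True, p=weights / total)
    template = stack.template
    pts = [(*template.cell_center(int(rows[i]), int(cols[i])), "synthetic")
           for i in idx]
    return OccurrenceSet(pts, "synthetic")


def landscape_and_presences(spec: SyntheticSpec) -> Tuple[EnvStack, OccurrenceSet]:
    """Convenience: landscape plus presences drawn from ``spec.true_response``."""
    stack = make_landscape(spec)
    occ = sample_presences(stack, spec.true_response, spec.n_presences,
                           spec.seed, spec.intercept)
    return stack, occ
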