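"""Landscape-level pattern indices on categorical rasters.

Implements the six standard landscape metrics with their conventional
raster definitions: patch count (NP, 8-connected), patch density (PD,
patches per 100 ha), landscape shape index (LSI, total edge including the
landscape boundary over the edge of a maximally compact square), contagion
(CONTAG, from double-count 4-adjacencies), division (DIVISION, 1 minus the
summed squared patch-area proportions) and Shannon evenness (SHEI).
Natural logarithms throughout; 0·ln 0 terms contribute zero. CONTAG and
SHEI are undefined (NaN, with a warning) on single-class landscapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np
from scipy import ndimage

from .grids import GridLayer

__all__ = ["MetricsReport", "metrics"]


class MetricsError(ValueError):
    pass


@dataclass
class MetricsReport:
    NP: int
    PD: float          # patches per 100 ha
    LSI: float
    CONTAG: float      # percent, NaN if m == 1
    DIVISION: float
    SHEI: float        # NaN if m == 1
    m: int             # number of classes present
    A: float           # landscape area, m^2

    def as_dict(self) -> Dict[str, float]:
        return {
            "NP": self.NP, "PD": self.PD, "LSI": self.LSI,
            "CONTAG": self.CONTAG, "DIVISION": self.DIVISION, "SHEI": self.SHEI,
            "m": self.m, "A": self.A,
        }


_EIGHT = np.ones((3, 3), int)


def _total_edge(classes: np.ndarray, valid: np.ndarray, cellsize: float,
                include_boundary: bool = True) -> float:
    """Total edge length: cell faces separating different classes, plus the
    landscape (and nodata) boundary when requested."""
    edge = 0.0
    work = np.where(valid, classes, -1)
    # internal vertical faces
    diff_h = work[:, 1:] != work[:, :-1]
    both_valid_h = valid[:, 1:] & valid[:, :-1]
    edge += np.count_nonzero(diff_h & both_valid_h) * cellsize
    diff_v = work[1:, :] != work[:-1, :]
    both_valid_v = valid[1:, :] & valid[:-1, :]
    edge += np.count_nonzero(diff_v & both_valid_v) * cellsize
    if include_boundary:
        # faces between a valid cell and outside / nodata
        boundary = 0
        boundary += np.count_nonzero(valid[0, :]) + np.count_nonzero(valid[-1, :])
        boundary += np.count_nonzero(valid[:, 0]) + np.count_nonzero(valid[:, -1])
        # internal nodata contacts
        boundary += np.count_nonzero((valid[:, 1:] != valid[:, :-1]))
        boundary += np.count_nonzero((valid[1:, :] != valid[:-1, :]))
        edge += boundary * cellsize
    return edge


def metrics(classified: GridLayer, cellsize: float | None = None,
            include_boundary: bool = True) -> MetricsReport:
    """Compute the six landscape metrics for one categorical raster."""
    if classified.kind != "categorical":
        raise MetricsError("metrics expects a categorical raster")
    cs = classified.cellsize if cellsize is None else cellsize
    valid = classified.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise MetricsError("empty raster: no valid cells")
    classes = classified.values.astype(int)
    present = sorted(set(classes[valid].tolist()))
    m = len(present)
    A = n_valid * cs * cs  # m^2
    cell_area = cs * cs

    # --- NP and DIVISION over 8-connected patches of every class
    np_total = 0
    division_sum = 0.0
    for c in present:
        lab, n = ndimage.label((classes == c) & valid, structure=_EIGHT)
        np_total += n
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            division_sum += float((((sizes * cell_area) / A) ** 2).sum())
    DIVISION = 1.0 - division_sum

    # --- PD: patches per 100 ha = NP / A(m^2) * 10^4 * 10^2
    PD = np_total / A * 1e4 * 1e2

    # --- LSI: 0.25 * E* / sqrt(A)
    E_star = _total_edge(classes, valid, cs, include_boundary)
    LSI = 0.25 * E_star / np.sqrt(A)

    # --- class proportions
    counts = np.array([np.count_nonzero((classes == c) & valid) for c in present],
                      dtype=float)
    P = counts / counts.sum()

    # --- SHEI
    if m == 1:
        warnings.warn("single-class landscape: SHEI and CONTAG undefined")
        SHEI = float("nan")
        CONTAG = float("nan")
    else:
        SHEI = float(-(P * np.log(P)).sum() / np.log(m))
        # --- CONTAG from double-count 4-adjacency
        idx = {c: i for i, c in enumerate(present)}
        g = np.zeros((m, m))
        remap = np.vectorize(lambda v: idx.get(v, -1))(classes)
        remap = np.where(valid, remap, -1)
        for (sl_a, sl_b) in ((np.s_[:, 1:], np.s_[:, :-1]), (np.s_[1:, :], np.s_[:-1, :])):
            a, b = remap[sl_a].ravel(), remap[sl_b].ravel()
            ok = (a >= 0) & (b >= 0)
            np.add.at(g, (a[ok], b[ok]), 1)
            np.add.at(g, (b[ok], a[ok]), 1)
        row_sums = g.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_ik = P[:, None] * np.where(row_sums > 0, g / row_sums, 0.0)
        terms = np.zeros_like(p_ik)
        pos = p_ik > 0
        terms[pos] = p_ik[pos] * np.log(p_ik[pos])  # 0 ln 0 := 0
        CONTAG = float((1.0 + terms.sum() / (2.0 * np.log(m))) * 100.0)

    return MetricsReport(np_total, float(PD), float(LSI), CONTAG,
                         float(DIVISION), SHEI, m, float(A))
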