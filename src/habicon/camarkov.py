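"""Markov projection of land-class areas and cellular-automata allocation.

The Markov step projects class areas with a row-stochastic transition
matrix estimated by cross-tabulating two calibration maps; one step spans
the interval between those maps. An optional scenario adjustment scales
every off-diagonal transition probability and renormalizes through the
diagonal — an explicit, minimal mechanism for exploring accelerated or
damped change.

Spatial allocation moves cells between classes until per-class counts hit
the projected targets exactly, preferring cells with a high same-class
neighbourhood fraction (optionally blended with a suitability score), so
growing classes expand from their existing patches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridLayer, distance_to_class

__all__ = [
    "TransitionMatrix",
    "AreaVector",
    "estimate_transition",
    "markov_project",
    "scenario_adjust",
    "ca_allocate",
    "refresh_distance_layers",
]


class CAMarkovError(ValueError):
    pass


@dataclass
class TransitionMatrix:
    """Row-stochastic per-step land-class transition probabilities."""

    classes: List[int]
    P: np.ndarray
    step_years: float = 0.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.classes)
        if self.P.shape != (k, k):
            raise CAMarkovError(f"P must be {k}x{k}")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise CAMarkovError("transition probabilities must lie in [0,1]")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise CAMarkovError("rows must sum to 1")

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.P, index=self.classes, columns=self.classes)
        df.index.name = "from_class"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str, step_years: float = 0.0) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        classes = [int(c) for c in df.index]
        return cls(classes, df.to_numpy(dtype=float), step_years)


@dataclass
class AreaVector:
    """Per-class areas (km² or cell counts) for one epoch."""

    classes: List[int]
    areas: np.ndarray
    epoch: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.classes),):
            raise CAMarkovError("areas length must match classes")
        if np.any(self.areas < 0):
            raise CAMarkovError("areas must be non-negative")

    @property
    def total(self) -> float:
        return float(self.areas.sum())

    def as_dict(self) -> Dict[int, float]:
        return {c: float(a) for c, a in zip(self.classes, self.areas)}


def estimate_transition(
    map_t1: GridLayer, map_t2: GridLayer, step_years: float = 0.0
) -> TransitionMatrix:
    """Cross-tabulate two aligned categorical maps and row-normalize.

    Classes seen in either map share one codebook; classes with no cells at
    t1 get an identity row (no evidence of leaving).
    """
    if map_t1.kind != "categorical" or map_t2.kind != "categorical":
        raise CAMarkovError("both maps must be categorical")
    if not map_t1.same_geometry(map_t2):
        raise CAMarkovError("maps are not aligned")
    joint = map_t1.valid_mask & map_t2.valid_mask
    a = map_t1.values[joint].astype(int)
    b = map_t2.values[joint].astype(int)
    classes = sorted(set(a.tolist()) | set(b.tolist()))
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k))
    np.add.at(counts, (np.vectorize(index.get)(a), np.vectorize(index.get)(b)), 1)
    P = np.zeros_like(counts)
    for i in range(k):
        row_sum = counts[i].sum()
        if row_sum > 0:
            P[i] = counts[i] / row_sum
        else:
            P[i, i] = 1.0
    return TransitionMatrix(classes, P, step_years)


def markov_project(areas: AreaVector, tm: TransitionMatrix, n_steps: int = 1) -> AreaVector:
    """Project class areas ``S_{t+n} = S_t · Pⁿ``; total area is conserved."""
    if areas.classes != tm.classes:
        raise CAMarkovError("area vector classes do not match the transition matrix")
    if n_steps < 0:
        raise CAMarkovError("n_steps must be non-negative")
    out = areas.areas @ np.linalg.matrix_power(tm.P, n_steps)
    return AreaVector(list(tm.classes), out, epoch=f"{areas.epoch}+{n_steps}step")


def scenario_adjust(tm: TransitionMatrix, multiplier: float) -> TransitionMatrix:
    """Scale off-diagonal transitions and renormalize via the diagonal."""
    if multiplier < 0:
        raise CAMarkovError("multiplier must be non-negative")
    P = tm.P.copy()
    k = P.shape[0]
    off = P * multiplier
    np.fill_diagonal(off, 0.0)
    diag = 1.0 - off.sum(axis=1)
    if np.any(diag < -1e-12):
        raise CAMarkovError(
            f"multiplier {multiplier} drives a diagonal negative; rows would "
            "not be stochastic"
        )
    out = off
    out[np.arange(k), np.arange(k)] = np.clip(diag, 0.0, 1.0)
    return TransitionMatrix(tm.classes, out, tm.step_years)


def _class_scores(
    current: np.ndarray,
    classes: Sequence[int],
    valid: np.ndarray,
    kernel: int,
    suitability: Optional[Dict[int, np.ndarray]] = None,
    blend: float = 0.5,
) -> Dict[int, np.ndarray]:
    """Per-class neighbourhood same-class fraction, optionally blended."""
    scores: Dict[int, np.ndarray] = {}
    # normalize by the in-window valid count so border cells are not
    # penalized by the implicit zero padding
    denom = ndimage.uniform_filter(valid.astype(float), size=kernel,
                                   mode="constant")
    denom = np.where(denom > 0, denom, 1.0)
    for c in classes:
        indicator = ((current == c) & valid).astype(float)
        frac = ndimage.uniform_filter(indicator, size=kernel, mode="constant") / denom
        if suitability is not None and c in suitability:
            frac = (1 - blend) * frac + blend * suitability[c]
        scores[c] = frac
    return scores


def ca_allocate(
    current: GridLayer,
    targets: AreaVector,
    suitability_stack: Optional[Dict[int, GridLayer]] = None,
    iterations: int = 10,
    kernel: int = 5,
    seed: int = 0,
    blend: float = 0.5,
) -> GridLayer:
    """Reallocate cells so per-class counts equal ``targets`` exactly.

    ``targets.areas`` are cell counts summing to the valid-cell count.
    Each iteration, classes above target shed their lowest-scoring cells
    into a pool and classes below target claim the highest-scoring pool
    cells; a seeded random jitter breaks score ties, so the result is
    deterministic for a given seed. Targets equal to the current counts
    leave the map untouched.
    """
    if current.kind != "categorical":
        raise CAMarkovError("current map must be categorical")
    if kernel % 2 != 1 or kernel < 1:
        raise CAMarkovError("kernel size must be odd and positive")
    valid = current.valid_mask
    n_valid = int(valid.sum())
    tgt = {c: int(round(a)) for c, a in targets.as_dict().items()}
    if any(v < 0 for v in tgt.values()):
        raise CAMarkovError("negative target count")
    if sum(tgt.values()) != n_valid:
        raise CAMarkovError(
            f"target cell counts sum to {sum(tgt.values())}, grid has {n_valid} valid cells"
        )
    work = current.values.astype(int).copy()
    classes = list(tgt)
    rng = np.random.default_rng(seed)

    suit_arrays = None
    if suitability_stack is not None:
        suit_arrays = {c: lay.values for c, lay in suitability_stack.items()}

    for it in range(iterations):
        counts = {c: int(((work == c) & valid).sum()) for c in classes}
        deficit = {c: tgt[c] - counts[c] for c in classes}
        if all(d == 0 for d in deficit.values()):
            break
        remaining_iters = iterations - it
        scores = _class_scores(work, classes, valid, kernel, suit_arrays, blend)
        jitter = rng.random(work.shape) * 1e-9

        # shed from over-target classes
        pool_rows: List[np.ndarray] = []
        pool_cols: List[np.ndarray] = []
        for c in classes:
            surplus = -deficit[c]
            if surplus <= 0:
                continue
            move = int(np.ceil(surplus / remaining_iters))
            members = np.nonzero((work == c) & valid)
            order = np.argsort(scores[c][members] + jitter[members])
            take = order[:move]
            pool_rows.append(members[0][take])
            pool_cols.append(members[1][take])
        if not pool_rows:
            break
        pr = np.concatenate(pool_rows)
        pc = np.concatenate(pool_cols)
        free = np.ones(pr.size, dtype=bool)

        # claim by under-target classes, neediest first
        for c in sorted(classes, key=lambda c: -deficit[c]):
            need = deficit[c]
            if need <= 0:
                continue
            take_n = min(need, int(free.sum()))
            if take_n == 0:
                continue
            avail = np.nonzero(free)[0]
            sc = scores[c][pr[avail], pc[avail]] + jitter[pr[avail], pc[avail]]
            chosen = avail[np.argsort(-sc)[:take_n]]
            work[pr[chosen], pc[chosen]] = c
            free[chosen] = False
    counts = {c: int(((work == c) & valid).sum()) for c in classes}
    if counts != tgt:
        # final corrective pass: force exact counts
        for c in classes:
            while counts[c] > tgt[c]:
                # move one lowest-score member to the neediest class
                needy = max(classes, key=lambda d: tgt[d] - counts[d])
                scores = _class_scores(work, [c], valid, kernel, suit_arrays, blend)
                members = np.nonzero((work == c) & valid)
                j = int(np.argmin(scores[c][members]))
                work[members[0][j], members[1][j]] = needy
                counts[c] -= 1
                counts[needy] += 1
    return GridLayer(work.astype(float), current.cellsize, current.origin,
                     current.nodata_mask.copy(), current.crs_tag, "categorical")


def refresh_distance_layers(
    projected_lucc: GridLayer,
    water_codes: Sequence[int],
    grassland_codes: Sequence[int],
) -> Tuple[GridLayer, GridLayer]:
    """Regenerate (DW, DH) distance rasters from a projected land-cover map."""
    dw = distance_to_class(projected_lucc, water_codes)
    dh = distance_to_class(projected_lucc, grassland_codes)
    return dw, dh
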