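"""Loading, de-duplication, and spatial thinning of occurrence points.

Coordinates are projected metres. Thinning is greedy in a seeded random
order, so "one is kept randomly" among any cluster of mutually-close
points; the retained set is always maximal (no discarded point could be
re-added without breaking the minimum distance).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

__all__ = ["OccurrenceSet", "load_points", "thin"]


class OccurrenceError(ValueError):
    pass


@dataclass
class OccurrenceSet:
    """Projected occurrence points ``(x, y, source_tag)``."""

    points: List[Tuple[float, float, str]] = field(default_factory=list)
    crs_tag: str = ""

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def xy(self) -> np.ndarray:
        """``(n, 2)`` coordinate array."""
        if not self.points:
            return np.empty((0, 2))
        return np.array([(p[0], p[1]) for p in self.points], dtype=float)

    def to_csv(self, path: str, kept: "OccurrenceSet | None" = None) -> None:
        """Write points; with ``kept`` given, add a 0/1 ``kept`` audit column."""
        kept_set = None
        if kept is not None:
            kept_set = {(p[0], p[1]) for p in kept.points}
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            header = ["x", "y", "source"]
            if kept_set is not None:
                header.append("kept")
            writer.writerow(header)
            for x, y, tag in self.points:
                row = [repr(x), repr(y), tag]
                if kept_set is not None:
                    row.append(int((x, y) in kept_set))
                writer.writerow(row)


def load_points(path: str, crs_tag: str = "", allow_lonlat: bool = False) -> OccurrenceSet:
    """Load an ``x,y[,source]`` CSV; exact duplicate coordinates collapse.

    Coordinates that all look like geographic lon/lat (|x| <= 180 and
    |y| <= 90) are refused unless ``allow_lonlat`` — distances in degrees
    would make the 100 m thinning rule meaningless.
    """
    points: List[Tuple[float, float, str]] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise OccurrenceError(f"{path}: empty file")
        cols = [h.strip().lower() for h in header]
        if "x" not in cols or "y" not in cols:
            raise OccurrenceError(f"{path}: CSV must have 'x' and 'y' columns")
        ix, iy = cols.index("x"), cols.index("y")
        isrc = cols.index("source") if "source" in cols else None
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            try:
                x = float(row[ix])
                y = float(row[iy])
            except (ValueError, IndexError):
                raise OccurrenceError(f"{path}: non-numeric coordinate on row {lineno}")
            tag = row[isrc].strip() if isrc is not None and len(row) > isrc else ""
            key = (x, y)
            if key in seen:
                continue
            seen.add(key)
            points.append((x, y, tag))
    if points and not allow_lonlat:
        xs = np.array([p[0] for p in points])
        ys = np.array([p[1] for p in points])
        if np.all(np.abs(xs) <= 180) and np.all(np.abs(ys) <= 90):
            raise OccurrenceError(
                f"{path}: coordinates look like lon/lat degrees; project them "
                "to metres first or pass allow_lonlat=True"
            )
    return OccurrenceSet(points, crs_tag)


def thin(occ: OccurrenceSet, min_dist: float = 100.0, seed: int = 0) -> OccurrenceSet:
    """Greedy randomized spatial thinning.

    Points are visited in a seeded shuffle order; a point is kept iff it is
    at least ``min_dist`` from every already-kept point. Deterministic for a
    given seed; output order follows the input order.
    """
    if min_dist <= 0:
        raise OccurrenceError("min_dist must be positive")
    n = len(occ)
    if n == 0:
        return OccurrenceSet([], occ.crs_tag)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    xy = occ.xy()
    kept_idx: List[int] = []
    for i in order:
        p = xy[i]
        ok = True
        for j in kept_idx:
            if np.hypot(p[0] - xy[j][0], p[1] - xy[j][1]) < min_dist:
                ok = False
                break
        if ok:
            kept_idx.append(int(i))
    kept_idx.sort()
    return OccurrenceSet([occ.points[i] for i in kept_idx], occ.crs_tag)
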