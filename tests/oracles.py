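"""Independent reference implementations used to cross-check the package.

These stay deliberately naive (brute force, library calls, closed forms)
and share no code with the implementations they verify.
"""

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as csgraph_dijkstra


def brute_force_distance(is_source: np.ndarray, cellsize: float) -> np.ndarray:
    """All-pairs nearest-source scan (centre-to-centre)."""
    nrows, ncols = is_source.shape
    src = np.argwhere(is_source)
    out = np.empty((nrows, ncols))
    for r in range(nrows):
        for c in range(ncols):
            d2 = ((src[:, 0] - r) ** 2 + (src[:, 1] - c) ** 2).min()
            out[r, c] = np.sqrt(d2) * cellsize
    return out


def flood_fill_patches(binary: np.ndarray, connectivity: int = 8) -> int:
    """Count connected components by explicit stack-based flood fill."""
    seen = np.zeros(binary.shape, dtype=bool)
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    nrows, ncols = binary.shape
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in offsets:
                    nr, nc = r + dr, c + dc
                    if (0 <= nr < nrows and 0 <= nc < ncols
                            and binary[nr, nc] and not seen[nr, nc]):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
    return count


def csgraph_cost_distance(resistance: np.ndarray, valid: np.ndarray,
                          source_cells, cellsize: float) -> np.ndarray:
    """Cost distance via scipy's csgraph Dijkstra on the 8-connected lattice
    with average-resistance step weights."""
    nrows, ncols = resistance.shape
    n = nrows * ncols
    rows, cols, data = [], [], []
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            for dr, dc in [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                           (0, 1), (1, -1), (1, 0), (1, 1)]:
                nr, nc = r + dr, c + dc
                if 0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc]:
                    d = cellsize * (np.sqrt(2.0) if dr and dc else 1.0)
                    w = d * (resistance[r, c] + resistance[nr, nc]) / 2.0
                    rows.append(r * ncols + c)
                    cols.append(nr * ncols + nc)
                    data.append(w)
    graph = csr_matrix((data, (rows, cols)), shape=(n, n))
    idx = [r * ncols + c for r, c in source_cells]
    dist = csgraph_dijkstra(graph, directed=False, indices=idx).min(axis=0)
    return dist.reshape(nrows, ncols)


def golden_section_maxent_1d(f_pres_mean: float, f_bg: np.ndarray) -> float:
    """Unregularized single-feature maxent coefficient by 1-D convex
    minimization of the negative gain."""

    def neg_gain(lam: float) -> float:
        return -(lam * f_pres_mean - np.log(np.mean(np.exp(lam * f_bg))))

    res = minimize_scalar(neg_gain, bracket=(-10.0, 0.0, 10.0), method="golden",
                          options={"xtol": 1e-10})
    return float(res.x)


def exhaustive_pearson_rule(names, corr: np.ndarray, contributions,
                            threshold: float):
    """Reference screening: walk pairs in descending |r|, drop the
    lower-contribution member unless one is already dropped."""
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((abs(corr[i, j]), names[i], names[j]))
    pairs.sort(key=lambda t: -t[0])
    dropped = set()
    for r, a, b in pairs:
        if r < threshold or a in dropped or b in dropped:
            continue
        dropped.add(a if contributions[a] < contributions[b] else b)
    return [n for n in names if n not in dropped]
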