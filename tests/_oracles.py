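"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use the slowest, most literal formulation of each
definition (double loops over voxel pairs, breadth-first flood fill,
per-feature Python sums) and share no code with the package internals.
"""

from collections import deque

import numpy as np


def brute_force_glcm(levels: np.ndarray, distance: int = 1) -> np.ndarray:
    """Enumerate every ordered voxel pair at the 26 offsets of the given
    distance; both voxels must be in-mask (level > 0).  Returns the
    normalized symmetric co-occurrence matrix."""
    L = int(levels.max())
    counts = np.zeros((L, L), dtype=np.int64)
    shape = levels.shape
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = levels[z, y, x]
                if a == 0:
                    continue
                for dz, dy, dx in offsets:
                    z2, y2, x2 = z + distance * dz, y + distance * dy, x + distance * dx
                    if not (0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2]):
                        continue
                    b = levels[z2, y2, x2]
                    if b == 0:
                        continue
                    counts[a - 1, b - 1] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def flood_fill_zones(levels: np.ndarray, connectivity: int = 26) -> list[tuple[int, int]]:
    """BFS flood fill returning (level, size) for every equal-level zone."""
    if connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if levels[z, y, x] == 0 or seen[z, y, x]:
                    continue
                level = levels[z, y, x]
                size = 0
                queue = deque([(z, y, x)])
                seen[z, y, x] = True
                while queue:
                    cz, cy, cx = queue.popleft()
                    size += 1
                    for dz, dy, dx in offsets:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]
                            and not seen[nz, ny, nx] and levels[nz, ny, nx] == level
                        ):
                            seen[nz, ny, nx] = True
                            queue.append((nz, ny, nx))
                zones.append((int(level), size))
    return zones


def zones_to_matrix(zones, n_levels: int) -> np.ndarray:
    max_size = max((s for _, s in zones), default=1)
    counts = np.zeros((n_levels, max_size), dtype=np.int64)
    for level, size in zones:
        counts[level - 1, size - 1] += 1
    return counts


def brute_force_bw(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Literal double-loop between/within sums of squares per feature."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        col = X[:, j]
        overall = sum(col) / n
        between = 0.0
        within = 0.0
        for c in set(y.tolist()):
            group = [col[i] for i in range(n) if y[i] == c]
            gmean = sum(group) / len(group)
            between += len(group) * (gmean - overall) ** 2
            within += sum((v - gmean) ** 2 for v in group)
        out[j] = between / within if within > 0 else (np.inf if between > 0 else 0.0)
    return out


def hull_membership_solidity(mask: np.ndarray) -> float:
    """Solidity via convex-hull facet inequalities (independent of Delaunay)."""
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask)
    hull = ConvexHull(pts)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)], indexing="ij")
    cand = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    # A point is inside iff it satisfies every facet inequality Ax + b <= 0
    A = hull.equations[:, :3]
    b = hull.equations[:, 3]
    inside = np.all(cand @ A.T + b <= 1e-9, axis=1)
    return pts.shape[0] / int(inside.sum())
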