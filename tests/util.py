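"""Independent oracles shared by the test suite.

Each helper is deliberately written from first principles (enumeration,
brute force, hand formulas) and stays independent of the package code paths
it is used to check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def exact_accumulation(species: list, max_t: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and sd of cumulative richness over ALL record orderings.

    Enumeration over permutations; feasible for <= 8 records.  Returns
    (mean S(t), sd S(t)) for t = 1..n.
    """
    n = len(species)
    if n > 8:
        raise ValueError("enumeration oracle limited to 8 records")
    t_max = max_t or n
    curves = []
    for perm in permutations(range(n)):
        seen: set = set()
        curve = []
        for idx in perm[:t_max]:
            seen.add(species[idx])
            curve.append(len(seen))
        curves.append(curve)
    curves = np.array(curves, dtype=float)
    return curves.mean(axis=0), curves.std(axis=0)


def brute_force_knn(points: np.ndarray, k_max: int) -> np.ndarray:
    """O(n^2) mean k-th nearest neighbor distances."""
    pts = np.asarray(points, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    dist.sort(axis=1)
    return dist[:, :k_max].mean(axis=0)


def brute_force_distance_transform(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """All-pairs nearest-mask-cell distance (cell centers), in meters."""
    mask = np.asarray(mask, dtype=bool)
    targets = np.argwhere(mask)
    out = np.empty(mask.shape)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            d2 = ((targets - np.array([i, j])) ** 2).sum(axis=1)
            out[i, j] = np.sqrt(d2.min()) * cell_size
    return out


def hand_kruskal_h(groups: list[list[float]]) -> float:
    """Kruskal-Wallis H from the rank formula, with tie correction."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    rank_of_value = {}
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        rank_of_value[sorted_vals[i]] = (i + 1 + j) / 2.0
        i = j
    ranks = np.array([rank_of_value[v] for v in pooled])
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * r.mean() ** 2
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def brute_force_schoener(p: np.ndarray, q: np.ndarray) -> float:
    total = 0.0
    for pi, qi in zip(np.ravel(p), np.ravel(q)):
        total += abs(pi - qi)
    return 1.0 - 0.5 * total


def point_in_unit_square(x: float, y: float) -> bool:
    """Boundary-inclusive point-in-polygon oracle for the unit square."""
    return 0.0 <= x <= 1.0 and 0.0 <= y <= 1.0
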