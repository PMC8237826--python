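"""Average-Nearest-Neighbor (ANN) analysis of survey site locations.

The observed mean distance to the k-th nearest neighboring site
(k = 1..K) is compared against a randomization null that scatters the same
number of points uniformly inside the study polygon.  Because the null
inherits the polygon's edge effects, no analytic edge correction is
applied.  Sites whose own 1-NN distance falls below the null's expected
mean 1-NN distance are classified aggregated; the rest overdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

__all__ = ["AnnResult", "knn_distances", "ann_null", "classify_aggregation", "ann_analysis"]


@dataclass
class AnnResult:
    k: np.ndarray
    observed: np.ndarray  # mean k-NN distance per k
    null_low: np.ndarray  # 2.5% envelope
    null_median: np.ndarray
    null_high: np.ndarray  # 97.5% envelope
    null_expected_nn: float  # mean over randomizations of the mean 1-NN distance
    aggregated_fraction: float
    n_sites: int


def knn_distances(points: np.ndarray, k_max: int) -> np.ndarray:
    """Mean distance from each site to its k-th nearest other site, k = 1..k_max."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < k_max + 1:
        raise ValueError(f"need at least k_max+1={k_max + 1} sites, got {n}")
    dist, _ = cKDTree(pts).query(pts, k=k_max + 1)
    return dist[:, 1:].mean(axis=0)


def _nn_distances(points: np.ndarray) -> np.ndarray:
    dist, _ = cKDTree(points).query(points, k=2)
    return dist[:, 1]


def sample_in_polygon(
    polygon: BaseGeometry, n: int, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("polygon has zero area")
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((0, 2))
    for _ in range(max_tries):
        need = n - len(out)
        if need <= 0:
            break
        factor = max(2, int(np.ceil((maxx - minx) * (maxy - miny) / polygon.area)))
        cand = np.column_stack(
            [
                rng.uniform(minx, maxx, size=need * factor),
                rng.uniform(miny, maxy, size=need * factor),
            ]
        )
        inside = shapely.contains_xy(polygon, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[inside]])
    if len(out) < n:
        raise RuntimeError("rejection sampling failed; polygon too thin?")
    return out[:n]


def ann_null(
    polygon: BaseGeometry,
    n_sites: int,
    k_max: int,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Null k-NN curves from uniform point placements in the polygon.

    Returns (curves [n_iter x k_max], envelope quantiles [3 x k_max],
    expected mean 1-NN distance).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curves = np.empty((n_iter, k_max))
    for i in range(n_iter):
        pts = sample_in_polygon(polygon, n_sites, rng)
        curves[i] = knn_distances(pts, k_max)
    envelope = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
    return curves, envelope, float(curves[:, 0].mean())


def classify_aggregation(points: np.ndarray, null_expected_nn: float) -> float:
    """Fraction of sites whose own 1-NN distance is below (or ties) the null mean."""
    return float(np.mean(_nn_distances(np.asarray(points, dtype=float)) <= null_expected_nn))


def ann_analysis(
    points: np.ndarray,
    polygon: BaseGeometry,
    k_max: int | None = None,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AnnResult:
    """Full ANN workflow: observed curve, null envelope, aggregation fraction."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k_max is None:
        k_max = min(30, n - 1)
    observed = knn_distances(pts, k_max)
    _, envelope, expected_nn = ann_null(polygon, n, k_max, n_iter=n_iter, seed=seed)
    return AnnResult(
        k=np.arange(1, k_max + 1),
        observed=observed,
        null_low=envelope[0],
        null_median=envelope[1],
        null_high=envelope[2],
        null_expected_nn=expected_nn,
        aggregated_fraction=classify_aggregation(pts, expected_nn),
        n_sites=n,
    )
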