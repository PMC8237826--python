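"""Environmental coverage of well-sampled cells: Schoener's D overlap,
resampling null test, and coverage-surface fraction.

The null model redraws |well-sampled| cells uniformly without replacement
from all cells, rebuilds the sampled frequency surface on the shared bins,
and recomputes D; the one-sided lower-tail p-value is
(1 + #{D_null <= D_obs}) / (1 + n_iter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gapmeter.envspace import EnvSpace, build_env_space

__all__ = ["OverlapResult", "schoener_d", "null_test", "coverage_fraction"]


@dataclass
class OverlapResult:
    d_observed: float
    null_distribution: np.ndarray
    p_value: float
    n_sampled_cells: int
    coverage_fraction: float


def schoener_d(p: np.ndarray, q: np.ndarray) -> float:
    """D = 1 - 0.5 * sum|p_i - q_i| over two normalized frequency surfaces."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frequency surfaces are on mismatched bins")
    for name, arr in (("p", p), ("q", q)):
        if not np.isclose(arr.sum(), 1.0, atol=1e-8):
            raise ValueError(f"surface {name} is not normalized (sum={arr.sum()})")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def _flat_bins(space_all: EnvSpace, scores: np.ndarray) -> np.ndarray:
    """Flattened bin index of each cell on the all-cells histogram grid."""
    nx = len(space_all.edges_x) - 1
    ny = len(space_all.edges_y) - 1
    ix = np.clip(np.searchsorted(space_all.edges_x, scores[:, 0], side="right") - 1, 0, nx - 1)
    iy = np.clip(np.searchsorted(space_all.edges_y, scores[:, 1], side="right") - 1, 0, ny - 1)
    return ix * ny + iy


def null_test(
    space_all: EnvSpace,
    scores: np.ndarray,
    sampled_idx: np.ndarray,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> OverlapResult:
    """Test the D overlap of a sampled cell set against uniform redraws.

    ``scores`` are the (PC1, PC2) scores of ALL cells underlying
    ``space_all``; ``sampled_idx`` indexes the well-sampled cells within it.
    """
    sampled_idx = np.asarray(sampled_idx)
    n_cells = len(scores)
    m = len(sampled_idx)
    if m < 2:
        raise ValueError("need at least 2 well-sampled cells")
    if m > n_cells:
        raise ValueError("more well-sampled cells than cells in the space")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p_all = space_all.surface.ravel()
    bins = _flat_bins(space_all, np.asarray(scores, dtype=float))
    n_bins = p_all.size

    obs_counts = np.bincount(bins[sampled_idx], minlength=n_bins).astype(float)
    d_obs = float(1.0 - 0.5 * np.abs(obs_counts / m - p_all).sum())

    # Uniform draws without replacement via random-key argpartition.
    keys = rng.random((n_iter, n_cells))
    draws = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = np.empty(n_iter)
    for i in range(n_iter):
        counts = np.bincount(bins[draws[i]], minlength=n_bins)
        null[i] = 1.0 - 0.5 * np.abs(counts / m - p_all).sum()

    p_value = (1.0 + np.sum(null <= d_obs)) / (1.0 + n_iter)
    space_sampled = build_env_space(
        scores, subset=sampled_idx, edges=(space_all.edges_x, space_all.edges_y)
    )
    return OverlapResult(
        d_observed=d_obs,
        null_distribution=null,
        p_value=float(p_value),
        n_sampled_cells=m,
        coverage_fraction=coverage_fraction(space_all, space_sampled),
    )


def coverage_fraction(space_all: EnvSpace, space_sampled: EnvSpace) -> float:
    """Fraction of occupied all-cells bins that contain at least one sampled cell."""
    occupied = space_all.occupied
    if not occupied.any():
        raise ValueError("all-cells surface is empty")
    if space_sampled.counts.shape != space_all.counts.shape:
        raise ValueError("surfaces are on mismatched bins")
    covered = occupied & space_sampled.occupied
    return float(covered.sum() / occupied.sum())
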