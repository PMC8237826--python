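"""Two-axis environmental spaces: standardized PCA with varimax rotation,
binned frequency surfaces, and per-cell rarity scores.

The PCA standardizes variables to zero mean / unit variance, extracts the
leading components, and varimax-rotates the correlation-scaled loading
matrix (Kaiser normalization, classic pairwise-sweep algorithm).  Reported
scores are the rotated *standardized* component scores (unit variance,
uncorrelated), so ``scores @ loadings.T`` reconstructs the standardized data
up to rank truncation.  Components are ordered by post-rotation explained
variance and sign-fixed so the largest-magnitude loading is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PCAResult", "EnvSpace", "pca_varimax", "varimax", "build_env_space", "rarity"]


@dataclass
class PCAResult:
    loadings: np.ndarray  # variables x components (correlation-scaled)
    scores: np.ndarray  # cells x components, unit variance
    variance_explained: np.ndarray  # fraction of total variance per component
    rotation: np.ndarray  # orthonormal matrix applied (identity if unrotated)
    variables: list[str] = field(default_factory=list)
    dropped_variables: list[str] = field(default_factory=list)


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Varimax rotation matrix R for a p x k loading matrix.

    Classic pairwise planar-rotation algorithm: sweep all column pairs,
    rotating each pair by the angle that maximizes the varimax criterion,
    until the summed rotation angles of a sweep fall below ``tol``.
    """
    lam = np.array(loadings, dtype=float)
    p, k = lam.shape
    if k < 2:
        return np.eye(k)
    comm = np.sqrt(np.sum(lam**2, axis=1))
    if kaiser_normalize:
        nonzero = comm > 0
        lam[nonzero] = lam[nonzero] / comm[nonzero, None]
    rot = np.eye(k)
    for _ in range(max_sweeps):
        total_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = lam[:, i], lam[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (p * np.sum(u * v) - np.sum(u) * np.sum(v))
                den = p * np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2)
                angle = 0.25 * np.arctan2(num, den)
                if abs(angle) < 1e-15:
                    continue
                c, s = np.cos(angle), np.sin(angle)
                g = np.array([[c, -s], [s, c]])
                lam[:, [i, j]] = lam[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
                total_angle += abs(angle)
        if total_angle < tol:
            break
    return rot


def pca_varimax(
    matrix: np.ndarray,
    n_components: int = 2,
    rotate: bool = True,
    variables: list[str] | None = None,
) -> PCAResult:
    """Standardized PCA with optional varimax rotation of the leading components.

    Rows are cells, columns variables.  Constant variables are dropped with a
    warning; rows must be complete cases (drop/log upstream).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 cells")
    if np.isnan(x).any():
        raise ValueError("missing values: drop incomplete cells before PCA")
    names = list(variables) if variables is not None else [f"v{i}" for i in range(x.shape[1])]

    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant variable(s): {dropped}", stacklevel=2)
    x = x[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    n, p = x.shape
    if p < n_components:
        raise ValueError(f"only {p} usable variables for {n_components} components")

    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt.T[:, :n_components]
    s = s[:n_components]

    # Correlation-scaled loadings; guard against rank deficiency.
    lam = v * (s / np.sqrt(n - 1))
    t = np.zeros((n, n_components))  # standardized (unit-variance) scores
    ok = s > 1e-12 * max(s[0], 1.0)
    t[:, ok] = (u[:, :n_components][:, ok]) * np.sqrt(n - 1)

    rot = varimax(lam) if rotate else np.eye(n_components)
    lam = lam @ rot
    t = t @ rot

    # Order by post-rotation explained variance, then fix signs.
    var_expl = np.sum(lam**2, axis=0) / p
    order = np.argsort(-var_expl)
    lam, t, var_expl, rot = lam[:, order], t[:, order], var_expl[order], rot[:, order]
    signs = np.sign(lam[np.argmax(np.abs(lam), axis=0), np.arange(lam.shape[1])])
    signs[signs == 0] = 1.0
    lam *= signs
    t *= signs
    rot *= signs
    return PCAResult(lam, t, var_expl, rot, variables=names, dropped_variables=dropped)


@dataclass
class EnvSpace:
    """Binned 2-D frequency surface over shared PC1 x PC2 bin edges."""

    edges_x: np.ndarray
    edges_y: np.ndarray
    surface: np.ndarray  # n_bins x n_bins, sums to 1
    counts: np.ndarray  # raw cell counts per bin

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def bin_of(self, score: np.ndarray) -> tuple[int, int]:
        """Bin indices of a single (PC1, PC2) score; right edge closed."""
        i = _digitize(score[0], self.edges_x)
        j = _digitize(score[1], self.edges_y)
        return i, j


def _digitize(value: float, edges: np.ndarray) -> int:
    if value < edges[0] or value > edges[-1]:
        raise ValueError(f"score {value} outside histogram range")
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return min(idx, len(edges) - 2)


def shared_edges(scores: np.ndarray, n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges spanning the pooled score range of ALL cells (both axes)."""
    ex = np.linspace(scores[:, 0].min(), scores[:, 0].max(), n_bins + 1)
    ey = np.linspace(scores[:, 1].min(), scores[:, 1].max(), n_bins + 1)
    # Degenerate axes (all scores equal) still need a nonzero-width bin.
    if ex[0] == ex[-1]:
        ex = np.linspace(ex[0] - 0.5, ex[0] + 0.5, n_bins + 1)
    if ey[0] == ey[-1]:
        ey = np.linspace(ey[0] - 0.5, ey[0] + 0.5, n_bins + 1)
    return ex, ey


def build_env_space(
    scores: np.ndarray,
    subset: np.ndarray | None = None,
    n_bins: int = 100,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> EnvSpace:
    """Histogram the (PC1, PC2) scores of a cell set into a frequency surface.

    Edges are always derived from ALL cells (pass precomputed ``edges`` when
    binning a subset) so that surfaces of different subsets are comparable.
    """
    scores = np.asarray(scores, dtype=float)
    if edges is None:
        edges = shared_edges(scores, n_bins=n_bins)
    pts = scores if subset is None else scores[np.asarray(subset)]
    if len(pts) == 0:
        raise ValueError("empty cell set")
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=edges)
    return EnvSpace(edges[0], edges[1], counts / counts.sum(), counts)


def rarity(space_all: EnvSpace, scores: np.ndarray) -> np.ndarray:
    """Rarity in [0, 1] per cell: 1 - f(own bin) / f_max over the all-cells surface."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    f_max = space_all.counts.max()
    out = np.empty(len(scores))
    for idx, sc in enumerate(scores):
        i, j = space_all.bin_of(sc)
        out[idx] = 1.0 - space_all.counts[i, j] / f_max
    return out
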