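"""Rank-based bias tests: tie-corrected Kruskal-Wallis comparisons of
well-sampled cells against all cells on PC axes and rarity scores, with an
optional stratified (per-subregion) run.

The H statistic is computed directly from the rank formula
H = [12 / (N(N+1)) * sum n_i * Rbar_i^2] - 3(N+1), divided by the tie
correction 1 - sum(t^3 - t) / (N^3 - N); p-values come from the chi-squared
approximation with (groups - 1) degrees of freedom.  For tiny pooled samples
an exact permutation p-value is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import chi2, rankdata

__all__ = [
    "KWResult",
    "kruskal_wallis",
    "axis_bias_test",
    "rarity_bias_test",
    "stratified_bias_table",
]


@dataclass
class KWResult:
    h: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]
    tie_correction: float


def kruskal_wallis(groups: list[np.ndarray | list], exact: bool = False) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 nonempty groups.

    ``exact=True`` replaces the chi-squared p-value with the exact
    permutation distribution of H (only allowed for pooled N <= 12).
    """
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrs):
        raise ValueError("empty group")
    sizes = tuple(len(a) for a in arrs)
    pooled = np.concatenate(arrs)
    n = len(pooled)
    df = len(arrs) - 1

    if np.all(pooled == pooled[0]):
        return KWResult(0.0, df, 1.0, sizes, 1.0)

    h = _h_statistic(arrs)
    if exact:
        if n > 12:
            raise ValueError("exact mode limited to pooled N <= 12")
        p = _exact_p(arrs, pooled, h)
    else:
        p = float(chi2.sf(h, df))
    tie = _tie_correction(pooled)
    return KWResult(float(h), df, p, sizes, float(tie))


def _tie_correction(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def _h_statistic(arrs: list[np.ndarray]) -> float:
    pooled = np.concatenate(arrs)
    n = len(pooled)
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrs:
        r = ranks[start : start + len(a)]
        h += len(a) * r.mean() ** 2
        start += len(a)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / _tie_correction(pooled)


def _exact_p(arrs: list[np.ndarray], pooled: np.ndarray, h_obs: float) -> float:
    """Exact permutation p over all assignments of pooled values to groups."""
    if len(arrs) != 2:
        raise ValueError("exact mode implemented for two groups")
    n = len(pooled)
    n1 = len(arrs[0])
    idx = np.arange(n)
    count = 0
    total = 0
    for chosen in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(chosen)] = True
        h = _h_statistic([pooled[mask], pooled[~mask]])
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return count / total


def axis_bias_test(
    scores_all: np.ndarray,
    sampled_idx: np.ndarray,
    axis: int = 0,
    exclusive: bool = False,
) -> KWResult:
    """Two-group KW of sampled-cell axis scores vs all-cell axis scores.

    By default the reference group is ALL cells (sampled included); pass
    ``exclusive=True`` to compare against the complement instead.
    """
    scores_all = np.asarray(scores_all, dtype=float)
    sampled_idx = np.asarray(sampled_idx)
    values_all = scores_all[:, axis] if scores_all.ndim == 2 else scores_all
    sampled = values_all[sampled_idx]
    if exclusive:
        mask = np.ones(len(values_all), dtype=bool)
        mask[sampled_idx] = False
        reference = values_all[mask]
    else:
        reference = values_all
    return kruskal_wallis([sampled, reference])


def rarity_bias_test(
    rarity_all: np.ndarray, sampled_idx: np.ndarray, exclusive: bool = False
) -> KWResult:
    """KW test of sampled-cell rarity vs all-cell rarity."""
    return axis_bias_test(np.asarray(rarity_all, dtype=float), sampled_idx, exclusive=exclusive)


def stratified_bias_table(
    strata: dict[str, np.ndarray],
    scores: np.ndarray,
    rarity_scores: np.ndarray,
    sampled_mask: np.ndarray,
    min_sampled: int = 2,
) -> list[dict]:
    """Per-stratum bias summary rows (PC1/PC2/rarity KW tests).

    ``strata`` maps stratum name -> boolean cell mask; strata with fewer than
    ``min_sampled`` well-sampled cells are skipped with a reason.
    """
    sampled_mask = np.asarray(sampled_mask, dtype=bool)
    rows = []
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        idx_in = np.flatnonzero(sampled_mask[mask])
        row: dict = {"stratum": name, "n_well_sampled": int(len(idx_in))}
        if len(idx_in) < min_sampled:
            row["skipped"] = f"fewer than {min_sampled} well-sampled cells"
            rows.append(row)
            continue
        sc = scores[mask]
        ra = rarity_scores[mask]
        for axis in (0, 1):
            res = axis_bias_test(sc, idx_in, axis=axis)
            row[f"pc{axis + 1}_h"] = res.h
            row[f"pc{axis + 1}_p"] = res.p_value
        res = rarity_bias_test(ra, idx_in)
        row["rarity_h"] = res.h
        row["rarity_p"] = res.p_value
        rows.append(row)
    return rows
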