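"""Per-cell inventory completeness from sample-based species accumulation.

Every record counts as one independent sample.  The accumulation curve is
the mean cumulative species richness over random permutations of the record
order; the saturating model S(t) = a*t / (1 + b*t) is least-squares fitted
to that mean curve, and completeness is S_obs divided by the fitted
asymptote a/b.  A cell is classified well-sampled when it has more than
``min_records`` records AND completeness above ``min_completeness`` (both
strict), or when it hosts a trusted exhaustive local inventory.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AccumulationCurve",
    "ClenchFit",
    "WellSampledDecision",
    "Reason",
    "accumulation_curve",
    "clench",
    "fit_clench",
    "classify_well_sampled",
]


@dataclass
class AccumulationCurve:
    t: np.ndarray  # 1..n_records
    mean_richness: np.ndarray  # S-bar(t), averaged over permutations
    n_records: int
    s_obs: int


@dataclass
class ClenchFit:
    a: float
    b: float
    asymptote: float
    completeness: float  # raw ratio, may exceed 1
    completeness_clipped: float
    converged: bool
    residual_norm: float


class Reason(str, Enum):
    RECORDS_AND_COMPLETENESS = "records_and_completeness"
    TRUSTED_INVENTORY = "trusted_inventory"
    NOT_WELL_SAMPLED = "not_well_sampled"


@dataclass
class WellSampledDecision:
    n_records: int
    completeness: float | None
    has_trusted_inventory: bool
    decision: bool
    reason: Reason


def accumulation_curve(
    species: np.ndarray | list,
    n_orders: int = 100,
    seed: int | np.random.Generator = 0,
) -> AccumulationCurve:
    """Mean cumulative richness over ``n_orders`` random record orderings."""
    codes = np.unique(np.asarray(species), return_inverse=True)[1]
    n = len(codes)
    if n == 0:
        raise ValueError("need at least one record")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(n_orders):
        perm = codes[rng.permutation(n)]
        first = np.zeros(n, dtype=bool)
        first[np.unique(perm, return_index=True)[1]] = True
        total += np.cumsum(first)
    s_obs = int(codes.max()) + 1
    return AccumulationCurve(np.arange(1, n + 1), total / n_orders, n, s_obs)


def clench(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * t / (1.0 + b * t)


def fit_clench(curve: AccumulationCurve) -> ClenchFit:
    """Bounded least-squares fit of the saturating accumulation model.

    Initialized at a0 = S-bar(1) (initial accumulation rate) and
    b0 = a0 / S_obs (so the starting asymptote equals observed richness).
    """
    t = np.asarray(curve.t, dtype=float)
    s = np.asarray(curve.mean_richness, dtype=float)
    if len(np.unique(t)) < 3 or np.ptp(s) == 0:
        return ClenchFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, np.nan)
    a0 = max(s[0], 1e-6)
    b0 = max(a0 / curve.s_obs, 1e-9)
    try:
        res = least_squares(
            lambda p: clench(t, p[0], p[1]) - s,
            x0=[a0, b0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            method="trf",
        )
    except Exception:
        return ClenchFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, np.nan)
    if not res.success:
        return ClenchFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, np.nan)
    a, b = float(res.x[0]), float(res.x[1])
    asymptote = a / b
    completeness = curve.s_obs / asymptote
    return ClenchFit(
        a=a,
        b=b,
        asymptote=asymptote,
        completeness=completeness,
        completeness_clipped=min(completeness, 1.0),
        converged=True,
        residual_norm=float(np.linalg.norm(res.fun)),
    )


def classify_well_sampled(
    fit: ClenchFit | None,
    n_records: int,
    has_trusted_inventory: bool = False,
    min_records: int = 50,
    min_completeness: float = 0.7,
) -> WellSampledDecision:
    """Two-route rule: (records > 50 AND completeness > 0.7) OR trusted inventory."""
    completeness = None
    if fit is not None and fit.converged and np.isfinite(fit.completeness):
        completeness = fit.completeness
    if has_trusted_inventory:
        return WellSampledDecision(n_records, completeness, True, True, Reason.TRUSTED_INVENTORY)
    if completeness is not None and n_records > min_records and completeness > min_completeness:
        return WellSampledDecision(
            n_records, completeness, False, True, Reason.RECORDS_AND_COMPLETENESS
        )
    return WellSampledDecision(n_records, completeness, False, False, Reason.NOT_WELL_SAMPLED)
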