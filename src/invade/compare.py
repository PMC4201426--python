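"""Wilcoxon rank-sum comparisons of ED and BL across invasion categories.

The test statistic W is reported under the Mann–Whitney U convention:
the rank sum of the first sample minus ``n1(n1+1)/2``, i.e. the number
of (x, y) pairs with x > y (ties counted 1/2).  For small samples
(n1 + n2 <= 12) the p-value comes from exhaustive enumeration of all
rank assignments using midranks, which handles ties exactly; larger
samples use the normal approximation with tie correction and continuity
correction (via scipy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import StatusTable

__all__ = ["ComparisonResult", "wilcoxon_rank_sum", "compare_categories",
           "DEFAULT_PAIRS"]

log = logging.getLogger(__name__)

DEFAULT_PAIRS = (
    ("prohibited", "nonprohibited"),
    ("prohibited", "invasive"),
    ("prohibited", "permitted"),
    ("permitted", "invasive"),
)

_EXACT_LIMIT = 12


@dataclass
class ComparisonResult:
    metric: str
    group1: str
    group2: str
    median1: float
    median2: float
    n1: int
    n2: int
    W: float
    p: float
    method: str  # exact | normal-approx


def _exact_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """U of x over y and its exact permutation p, by enumerating all
    C(n1+n2, n1) rank assignments of the pooled midranks."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = np.array([
        ranks[list(c)].sum() - n1 * (n1 + 1) / 2.0
        for c in combinations(range(n1 + n2), n1)
    ])
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(u_obs), float(p)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float, str]:
    """Rank-sum test of two independent samples.

    Returns ``(W, p, method)`` with W the Mann–Whitney U of ``x`` over
    ``y`` (so ``W(x, y) + W(y, x) = n1 * n2``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if x.size + y.size <= _EXACT_LIMIT:
        w, p = _exact_p(x, y, alternative)
        return w, p, "exact"
    res = stats.mannwhitneyu(x, y, alternative=alternative,
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue), "normal-approx"


def compare_categories(metrics: pd.DataFrame, status: StatusTable,
                       metric: str = "ED",
                       pairs=DEFAULT_PAIRS,
                       alternative: str = "two-sided") -> pd.DataFrame:
    """Wilcoxon comparisons of one tip metric between category pairs.

    ``metrics`` is the species-indexed BL/ED table from
    :meth:`invade.phylo.Phylogeny.tip_metrics`.  Pairs with an empty
    category are skipped with a warning.
    """
    if metric not in metrics.columns:
        raise KeyError(f"metric {metric!r} not in metrics table")
    values = metrics[metric].dropna()
    rows = []
    for g1, g2 in pairs:
        s1 = values.reindex([s for s in status.members(g1)]).dropna()
        s2 = values.reindex([s for s in status.members(g2)]).dropna()
        if s1.empty or s2.empty:
            log.warning("skipping %s vs %s for %s: empty category", g1, g2, metric)
            continue
        w, p, method = wilcoxon_rank_sum(s1.to_numpy(), s2.to_numpy(), alternative)
        rows.append(ComparisonResult(metric, g1, g2,
                                     float(s1.median()), float(s2.median()),
                                     len(s1), len(s2), w, p, method))
    return pd.DataFrame([r.__dict__ for r in rows])
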