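"""Phylogenetic signal in a binary trait: the D statistic.

The statistic standardizes the observed sum of trait differences along
the tree against two reference distributions:

* a **random null** — the tip states shuffled across tips, destroying any
  phylogenetic structure (expected D = 1);
* a **Brownian null** — a continuous character evolved under Brownian
  motion on the same tree and thresholded so the number of 1-tips matches
  the data (expected D = 0).

The raw quantity is ``sum_d``: nodal trait values are estimated by
post-order averaging of child values, and ``sum_d`` is the sum over all
edges of the absolute parent–child difference.  Then

    D = (sum_d_obs - mean(sum_d_BM)) / (mean(sum_d_random) - mean(sum_d_BM))

D < 0 indicates a highly conserved trait, D ≈ 0 Brownian-like
conservation, D ≈ 1 random arrangement, D > 1 overdispersion.  Branch
lengths enter only through the Brownian simulation (child averaging is
unweighted and the threshold is rank-based), so D is invariant to
rescaling the tree.

Two one-tailed Monte-Carlo p-values accompany D, both in the
conservation direction: ``p_random`` is the fraction of random-null
``sum_d`` values at or below the observed one (small = more conserved
than random), and ``p_brownian`` the fraction of Brownian-null values at
or above it (small = less conserved than Brownian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Phylogeny

__all__ = ["SignalResult", "sum_sister_differences", "d_statistic", "interpret_d"]


@dataclass
class SignalResult:
    sum_d_obs: float
    d_value: float
    p_random: float
    p_brownian: float
    n_sims: int
    seed: int | None
    null_random: np.ndarray = field(repr=False)
    null_brownian: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "sum_d_obs": self.sum_d_obs,
            "d_value": self.d_value,
            "p_random": self.p_random,
            "p_brownian": self.p_brownian,
            "null_random_mean": float(np.mean(self.null_random)),
            "null_random_sd": float(np.std(self.null_random, ddof=1)),
            "null_brownian_mean": float(np.mean(self.null_brownian)),
            "null_brownian_sd": float(np.std(self.null_brownian, ddof=1)),
            "n_sims": self.n_sims,
            "seed": self.seed,
        }


def _states_vector(tree: Phylogeny, states) -> np.ndarray:
    """Binary state per tip, in tip order; validates coverage and dimorphism."""
    if isinstance(states, pd.Series):
        states = states.to_dict()
    missing = [t for t in tree.tip_names if t not in states]
    if missing:
        raise ValueError(f"missing tip states for {len(missing)} tips, e.g. {missing[:3]}")
    v = np.array([states[t] for t in tree.tip_names], dtype=float)
    if not np.isin(v, [0.0, 1.0]).all():
        raise ValueError("states must be binary 0/1")
    if v.min() == v.max():
        raise ValueError("trait is monomorphic: both states must be present")
    return v


def _sum_d_many(tree: Phylogeny, tip_states: np.ndarray) -> np.ndarray:
    """sum_d for each column of a (n_tips, S) matrix of binary tip states."""
    nodes = tree._nodes
    children = tree._children
    parent = tree._parent
    tip_ids = tree._tip_ids
    m = len(nodes)
    S = tip_states.shape[1]
    V = np.empty((m, S), dtype=float)
    V[tip_ids] = tip_states
    for i in range(m):
        kids = children[i]
        if kids:
            V[i] = V[kids].mean(axis=0)
    total = np.zeros(S)
    nonroot = parent >= 0
    total = np.abs(V[nonroot] - V[parent[nonroot]]).sum(axis=0)
    return total


def sum_sister_differences(tree: Phylogeny, states) -> float:
    """Observed sum over edges of |parent - child| nodal trait estimates."""
    v = _states_vector(tree, states)
    return float(_sum_d_many(tree, v[:, None])[0])


def _simulate_bm_tips(tree: Phylogeny, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-rate Brownian tip values, (n_tips, n_sims); variance ∝ branch length."""
    m = len(tree._nodes)
    eps = rng.standard_normal((m, n_sims)) * np.sqrt(tree._blen)[:, None]
    V = np.zeros((m, n_sims))
    for i in range(m - 1, -1, -1):  # parents before children
        p = tree._parent[i]
        V[i] = eps[i] + (V[p] if p >= 0 else 0.0)
    return V[tree._tip_ids]


def _threshold_top_k(values: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Binary matrix marking the k largest entries per column; ties broken at random."""
    spread = values.std(axis=0, keepdims=True) + 1e-300
    jitter = (rng.random(values.shape) - 0.5) * 1e-9 * spread
    order = np.argsort(values + jitter, axis=0)
    out = np.zeros_like(values)
    np.put_along_axis(out, order[-k:], 1.0, axis=0)
    return out


def d_statistic(tree: Phylogeny, states, n_sims: int = 1000,
                seed: int | None = None,
                resolve_polytomies: bool = False) -> SignalResult:
    """Compute D with ``n_sims`` random-shuffle and Brownian-threshold nulls.

    The tree must be strictly bifurcating; set ``resolve_polytomies=True``
    to resolve polytomies at random with zero-length edges first (the
    resolution is seeded from ``seed``).
    """
    if not tree.is_bifurcating():
        if not resolve_polytomies:
            raise ValueError(
                "tree contains polytomies; pass resolve_polytomies=True to "
                "randomly bifurcate them (seeded)"
            )
        tree = tree.resolve_polytomies(0 if seed is None else seed)
    v = _states_vector(tree, states)
    k = int(v.sum())
    rng = np.random.default_rng(seed)

    sum_d_obs = float(_sum_d_many(tree, v[:, None])[0])
    shuffled = rng.permuted(np.tile(v[:, None], (1, n_sims)), axis=0)
    null_random = _sum_d_many(tree, shuffled)
    bm_tips = _simulate_bm_tips(tree, n_sims, rng)
    bm_states = _threshold_top_k(bm_tips, k, rng)
    null_brownian = _sum_d_many(tree, bm_states)

    denom = null_random.mean() - null_brownian.mean()
    if abs(denom) < 1e-12:
        raise ValueError("degenerate nulls: random and Brownian means coincide")
    d_value = (sum_d_obs - null_brownian.mean()) / denom
    p_random = float(np.mean(null_random <= sum_d_obs))
    p_brownian = float(np.mean(null_brownian >= sum_d_obs))
    return SignalResult(sum_d_obs, float(d_value), p_random, p_brownian,
                        n_sims, seed, null_random, null_brownian)


def interpret_d(result: SignalResult, alpha: float = 0.05) -> str:
    """Plain-language label for which null(s) the trait departs from."""
    conserved_vs_random = result.p_random < alpha
    overdispersed_vs_random = (1.0 - result.p_random) < alpha
    departs_bm = result.p_brownian < alpha
    if overdispersed_vs_random and result.d_value > 1:
        return "over-dispersed"
    if conserved_vs_random and not departs_bm:
        if result.d_value < 0:
            return "highly conserved (beyond BM)"
        return "phylogenetically conserved (BM-like)"
    if departs_bm and not conserved_vs_random:
        return "random-like; departs from BM"
    if conserved_vs_random and departs_bm:
        return "intermediate: departs from both random and BM"
    return "indistinguishable from both random and BM"
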