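"""Community phylogenetic structure: NRI and NTI against a phylogeny-pool null.

For a set of species on a dated tree, MPD is the mean patristic distance
over all unordered pairs and MNTD the mean distance from each member to
its nearest other member.  Null communities of the same size are drawn
uniformly without replacement from all tree tips (the "phylogeny pool"
null).  The indices are minus the standardized effect sizes,

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

so phylogenetic clustering (short observed distances) is positive.  The
Monte-Carlo p-values use the add-one rank rule
``p = (1 + #{null <= obs}) / (n_reps + 1)`` and are one-tailed in the
clustering direction: small p means the set is more clustered than the
null; an overdispersed set has p near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, normalize_name
from .tables import StatusTable

__all__ = ["CommunityResult", "mpd", "mntd", "ses_community", "community_by_category"]


@dataclass
class CommunityResult:
    name: str
    n_members: int
    mpd_obs: float
    mntd_obs: float
    mpd_null_mean: float
    mpd_null_sd: float
    mntd_null_mean: float
    mntd_null_sd: float
    nri: float
    nti: float
    p_nri: float
    p_nti: float
    n_reps: int
    seed: int | None


def _member_index(dist: pd.DataFrame, members) -> np.ndarray:
    names = [normalize_name(m) for m in members]
    missing = [m for m in names if m not in dist.index]
    if missing:
        raise KeyError(f"species not in distance matrix: {missing[:5]}")
    if len(set(names)) < 2:
        raise ValueError("need at least 2 distinct member species")
    pos = {n: i for i, n in enumerate(dist.index)}
    return np.array([pos[m] for m in dict.fromkeys(names)], dtype=np.intp)


def mpd(dist: pd.DataFrame, members) -> float:
    """Mean pairwise patristic distance within a species set."""
    idx = _member_index(dist, members)
    sub = dist.to_numpy()[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub[np.triu_indices(k, 1)].mean())


def mntd(dist: pd.DataFrame, members) -> float:
    """Mean distance from each member to its nearest other member."""
    idx = _member_index(dist, members)
    sub = dist.to_numpy()[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mpd_many(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """MPD for each row of an (R, k) index matrix into D."""
    sub = D[idx[:, :, None], idx[:, None, :]]  # (R, k, k)
    k = idx.shape[1]
    return sub.sum(axis=(1, 2)) / (k * (k - 1))


def _mntd_many(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = D[idx[:, :, None], idx[:, None, :]].copy()
    k = idx.shape[1]
    sub[:, np.arange(k), np.arange(k)] = np.inf
    return sub.min(axis=2).mean(axis=1)


def ses_community(tree_or_dist: Phylogeny | pd.DataFrame, members,
                  n_reps: int = 1000, seed: int | None = None,
                  name: str = "community") -> CommunityResult:
    """NRI/NTI for one species set against the phylogeny-pool null.

    ``members`` must be a strict subset of the pool (all tips of the tree
    / rows of the distance matrix); the full set has a zero-variance null.
    """
    dist = (tree_or_dist.cophenetic_matrix()
            if isinstance(tree_or_dist, Phylogeny) else tree_or_dist)
    idx = _member_index(dist, members)
    D = dist.to_numpy()
    n_pool, k = D.shape[0], len(idx)
    if k >= n_pool:
        raise ValueError("member set equals the full pool: null has zero variance")

    rng = np.random.default_rng(seed)
    null_idx = np.argpartition(rng.random((n_reps, n_pool)), k - 1, axis=1)[:, :k]
    mpd_null = _mpd_many(D, null_idx)
    mntd_null = _mntd_many(D, null_idx)
    mpd_obs = _mpd_many(D, idx[None, :])[0]
    mntd_obs = _mntd_many(D, idx[None, :])[0]

    mpd_sd = mpd_null.std(ddof=1)
    mntd_sd = mntd_null.std(ddof=1)
    if mpd_sd < 1e-12 or mntd_sd < 1e-12:
        raise ValueError("null distance variance is ~0; pool too small or degenerate")
    nri = -(mpd_obs - mpd_null.mean()) / mpd_sd
    nti = -(mntd_obs - mntd_null.mean()) / mntd_sd
    p_nri = (1.0 + np.sum(mpd_null <= mpd_obs)) / (n_reps + 1.0)
    p_nti = (1.0 + np.sum(mntd_null <= mntd_obs)) / (n_reps + 1.0)
    return CommunityResult(name, k, float(mpd_obs), float(mntd_obs),
                           float(mpd_null.mean()), float(mpd_sd),
                           float(mntd_null.mean()), float(mntd_sd),
                           float(nri), float(nti), float(p_nri), float(p_nti),
                           n_reps, seed)


def community_by_category(tree: Phylogeny, status: StatusTable,
                          categories=("prohibited", "permitted", "invasive",
                                      "nonprohibited"),
                          n_reps: int = 1000,
                          seed: int | None = None) -> pd.DataFrame:
    """One NRI/NTI row per invasion category, all against the same pool.

    The pool is the full tip set of ``tree`` (the analyzed assemblage);
    categories with fewer than two species on the tree are skipped.
    """
    dist = tree.cophenetic_matrix()
    tips = set(tree.tip_names)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rows = []
    for cat, child in zip(categories, ss.spawn(len(categories))):
        members = [s for s in status.members(cat) if s in tips]
        if len(members) < 2 or len(members) >= len(tips):
            continue
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rows.append(ses_community(dist, members, n_reps=n_reps,
                                  seed=sub_seed, name=cat).__dict__)
    return pd.DataFrame(rows)
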