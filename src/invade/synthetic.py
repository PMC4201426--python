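"""Synthetic trees, status assignments, and trait tables with known structure.

Every downstream stage is testable without the real supertree or trait
compendium: this module generates inputs whose ground truth is known by
construction —

* dated trees (Yule or Kingman coalescent) with Myr-scale branch lengths;
* a binary prohibited/nonprohibited status with an exact prevalence and a
  controllable generating process: ``random`` (no structure, D ≈ 1),
  ``bm_threshold`` (Brownian-threshold evolution, D ≈ 0), or
  ``taxon_clustered`` (selection odds boosted inside designated families,
  reproducing taxonomic selectivity without tree-wide signal);
* families assigned to contiguous clades, so taxonomic and phylogenetic
  structure can be coupled or decoupled;
* trait tables with configurable logit-scale effects, family random
  intercepts, and missing data under a sentinel.

All generators are pure functions of their seed and configuration.  The
bundled default fixture mirrors the shape of the checklist analyzed in
the motivating study: 77 species in 20 families and 9 orders, with a
19 / 7 / 51 prohibited / permitted / invasive split (shape only; all
values are synthetic).
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy import special

from .dstat import _simulate_bm_tips, _threshold_top_k
from .phylo import Phylogeny
from .tables import CATEGORY_BY_APPENDIX, StatusTable, TraitTable

__all__ = [
    "SyntheticConfig", "simulate_tree", "assign_families", "simulate_status",
    "simulate_traits", "simulate_glmm_dataset", "make_default_fixture",
]

DEFAULT_N_SPECIES = 77
DEFAULT_N_FAMILIES = 20
DEFAULT_N_ORDERS = 9
DEFAULT_SPLIT = (19, 7, 51)  # prohibited / permitted / invasive


@dataclass
class SyntheticConfig:
    """One bundle of generator settings (defaults mirror the study shape)."""

    n_species: int = DEFAULT_N_SPECIES
    tree_model: str = "yule"
    status_mode: str = "taxon_clustered"
    prevalence: int = DEFAULT_SPLIT[0]
    n_permitted: int = DEFAULT_SPLIT[1]
    n_families: int = DEFAULT_N_FAMILIES
    n_orders: int = DEFAULT_N_ORDERS
    tree_depth: float = 100.0
    clustered_boost: float = 8.0
    trait_effects: dict[str, float] = field(default_factory=dict)
    intercept_sd: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.prevalence <= self.n_species - 1):
            raise ValueError("prevalence must be in [1, n_species - 1]")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")


def simulate_tree(n: int, model: str = "yule", seed: int | None = None,
                  depth: float = 100.0) -> Phylogeny:
    """Simulate a rooted binary tree with ``n`` uniquely named tips.

    ``yule`` gives an ultrametric pure-birth tree, ``coalescent`` a
    Kingman genealogy.  Branch lengths are rescaled so the maximum
    root-to-tip distance equals ``depth`` (default 100, i.e. Myr-scale).
    """
    if n < 3:
        raise ValueError("need at least 3 tips")
    rng = _random.Random(seed)
    if model == "yule":
        tree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                        num_extant_tips=n, rng=rng)
    elif model == "coalescent":
        ns = dendropy.TaxonNamespace([f"sp{i + 1:03d}" for i in range(n)])
        tree = treesim.pure_kingman_tree(taxon_namespace=ns, pop_size=1.0, rng=rng)
    else:
        raise ValueError(f"unknown tree model {model!r}")
    # deterministic tip names in traversal order
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label="")
        leaf.taxon.label = f"sp{i + 1:03d}"
    height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    scale = depth / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return Phylogeny(tree)


def assign_families(tree: Phylogeny, n_families: int,
                    n_orders: int | None = None) -> pd.DataFrame:
    """Label contiguous clades as families (and families as orders).

    The largest clade is split repeatedly until ``n_families`` groups of
    tips exist, so each family is monophyletic; consecutive families are
    then grouped into ``n_orders`` orders.  Returns a species-indexed
    DataFrame with ``family`` and ``order`` columns.
    """
    if n_families > tree.n_tips:
        raise ValueError("more families than species")
    dtree = tree.dendropy_tree
    groups = [dtree.seed_node]
    while len(groups) < n_families:
        groups.sort(key=lambda nd: -len(nd.leaf_nodes()))
        big = groups.pop(0)
        kids = big.child_nodes()
        if not kids:
            groups.append(big)
            break
        groups.extend(kids)
    rows = []
    groups.sort(key=lambda nd: min(lf.taxon.label for lf in nd.leaf_nodes()))
    n_orders = n_orders or max(1, len(groups) // 2)
    order_of_family = np.concatenate([
        np.full(len(chunk), oi)
        for oi, chunk in enumerate(np.array_split(np.arange(len(groups)),
                                                  min(n_orders, len(groups))))
    ])
    for gi, node in enumerate(groups):
        fam = f"fam{gi + 1:02d}"
        order = f"ord{order_of_family[gi] + 1:02d}"
        for leaf in node.leaf_nodes():
            rows.append({"species": leaf.taxon.label, "family": fam, "order": order})
    return pd.DataFrame(rows).set_index("species")


def _weighted_sample_without_replacement(weights: np.ndarray, k: int,
                                         rng: np.random.Generator) -> np.ndarray:
    """Efraimidis-Spirakis: top-k of u^(1/w) keys."""
    keys = rng.random(len(weights)) ** (1.0 / weights)
    return np.argsort(keys)[-k:]


def simulate_status(tree: Phylogeny, mode: str = "random",
                    prevalence: int = 10,
                    families: pd.DataFrame | None = None,
                    seed: int | None = None,
                    n_permitted: int = 0,
                    boosted_families: list[str] | None = None,
                    boost: float = 8.0,
                    n_families: int = DEFAULT_N_FAMILIES,
                    n_orders: int = DEFAULT_N_ORDERS) -> StatusTable:
    """Assign prohibited status to exactly ``prevalence`` species.

    Modes: ``random`` picks uniformly; ``bm_threshold`` evolves a
    Brownian character on the tree and marks the top-``prevalence`` tips
    (phylogenetically conserved status); ``taxon_clustered`` samples with
    odds multiplied by ``boost`` inside ``boosted_families`` (default:
    the largest family).  Among the nonprohibited, ``n_permitted``
    species are labeled appendix 2 (permitted), the rest appendix 3.
    """
    n = tree.n_tips
    if not (1 <= prevalence <= n - 1):
        raise ValueError("prevalence must be in [1, n_tips - 1]")
    if families is None:
        families = assign_families(tree, min(n_families, n), n_orders)
    families = families.loc[tree.tip_names]
    rng = np.random.default_rng(seed)

    if mode == "random":
        chosen = rng.choice(n, size=prevalence, replace=False)
    elif mode == "bm_threshold":
        vals = _simulate_bm_tips(tree, 1, rng)
        chosen = np.flatnonzero(_threshold_top_k(vals, prevalence, rng)[:, 0])
    elif mode == "taxon_clustered":
        fam = families["family"].to_numpy()
        if boosted_families is None:
            sizes = families["family"].value_counts()
            boosted_families = [sizes.index[0]]
        w = np.where(np.isin(fam, boosted_families), float(boost), 1.0)
        chosen = _weighted_sample_without_replacement(w, prevalence, rng)
    else:
        raise ValueError(f"unknown status mode {mode!r}")

    y = np.zeros(n, dtype=int)
    y[chosen] = 1
    appendix = np.full(n, 3, dtype=int)
    appendix[chosen] = 1
    nonpro = np.flatnonzero(y == 0)
    if n_permitted > len(nonpro):
        raise ValueError("n_permitted exceeds the nonprohibited count")
    if n_permitted:
        appendix[rng.choice(nonpro, size=n_permitted, replace=False)] = 2
    df = pd.DataFrame({
        "species": tree.tip_names,
        "family": families["family"].to_numpy(),
        "order": families["order"].to_numpy(),
        "appendix": appendix,
    })
    df["category"] = df["appendix"].map(CATEGORY_BY_APPENDIX)
    df["y"] = y
    return StatusTable(df)


def simulate_traits(status: StatusTable, effects: dict[str, float],
                    intercept_sd: float = 1.0,
                    missing: float = 0.0,
                    sentinel: float = -999.0,
                    seed: int | None = None,
                    regenerate_status: bool = True
                    ) -> tuple[TraitTable, StatusTable]:
    """Standard-normal traits with known logit-scale effects on status.

    Traits are drawn N(0, 1) per species.  When ``regenerate_status`` is
    true, a fresh binary response is drawn from the logistic model

        logit P(y=1) = b0 + sum_t effects[t] * trait_t + u_family,
        u_family ~ N(0, intercept_sd^2)

    with ``b0`` set so the expected prevalence matches the input table's;
    the returned status table carries this regenerated y (appendix 1 vs
    3), making the configured slopes the ground truth for the GLMM
    screen.  With ``regenerate_status=False`` the input status (and its
    exact prevalence and taxonomic structure) is accepted instead, and
    each effect acts as a standardized mean shift of that trait in the
    prohibited class — an association the screen can detect, without
    disturbing the status table.  Missing cells are inserted completely
    at random at rate ``missing`` (stored as NaN; written to CSV as the
    sentinel).
    """
    if not effects:
        raise ValueError("effects must name at least one trait")
    if not (0 <= missing < 1):
        raise ValueError("missing fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    species = status.data["species"].tolist()
    nsp = len(species)
    traits = pd.DataFrame(
        {t: rng.standard_normal(nsp) for t in effects},
        index=pd.Index(species, name="species"),
    )

    out_status = status
    if regenerate_status:
        fams, fam_names = pd.factorize(status.data["family"])
        u = rng.normal(0.0, intercept_sd, size=len(fam_names))
        b0 = special.logit(status.data["y"].mean())
        eta = b0 + sum(slope * traits[t].to_numpy()
                       for t, slope in effects.items()) + u[fams]
        y = (rng.random(nsp) < special.expit(eta)).astype(int)
        df = status.data.copy()
        df["y"] = y
        df["appendix"] = np.where(y == 1, 1, 3)
        df["category"] = df["appendix"].map(CATEGORY_BY_APPENDIX)
        out_status = StatusTable(df, status.excluded)
    else:
        y = status.data["y"].to_numpy()
        for t, slope in effects.items():
            traits[t] = traits[t] + slope * y

    if missing > 0:
        mask = rng.random(traits.shape) < missing
        traits = traits.mask(mask)
    return TraitTable(traits, sentinel), out_status


def simulate_glmm_dataset(n_groups: int = 50, group_size: int = 40,
                          slope: float = 0.5, intercept: float = 0.0,
                          sigma: float = 1.0,
                          seed: int | None = None) -> pd.DataFrame:
    """Balanced logistic random-intercept data for recovery tests.

    Returns a DataFrame with columns ``y``, ``x``, ``group`` generated
    from ``logit p = intercept + slope * x + u_g``, ``u_g ~ N(0, sigma^2)``,
    ``x ~ N(0, 1)``.
    """
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), group_size)
    x = rng.standard_normal(n_groups * group_size)
    u = rng.normal(0.0, sigma, size=n_groups)
    eta = intercept + slope * x + u[g]
    y = (rng.random(eta.size) < special.expit(eta)).astype(int)
    return pd.DataFrame({"y": y, "x": x, "group": [f"g{i:03d}" for i in g]})


def make_default_fixture(outdir: str | Path, seed: int = 20140430,
                         config: SyntheticConfig | None = None
                         ) -> dict[str, Path]:
    """Write the bundled tree/status/traits fixture set (tree.nwk,
    status.csv, traits.csv) and return the paths.

    The default configuration reproduces the shape of the motivating
    dataset — 77 species, 20 families, 9 orders, 19/7/51 split — with
    taxon-clustered prohibited status (selectivity without tree-wide
    signal) and six traits, two of which carry real effects.
    """
    cfg = config or SyntheticConfig(
        seed=seed,
        trait_effects={
            "gestation_len": -0.8,
            "group_size": 0.7,
            "body_mass": 0.0,
            "litter_size": 0.0,
            "latitude_range": 0.0,
            "home_range": 0.0,
        },
        missing_fraction=0.15,
    )
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_status, s_traits = (int(c.generate_state(1)[0] % (2**31))
                                  for c in ss.spawn(3))
    tree = simulate_tree(cfg.n_species, cfg.tree_model, seed=s_tree,
                         depth=cfg.tree_depth)
    status = simulate_status(tree, mode=cfg.status_mode,
                             prevalence=cfg.prevalence, seed=s_status,
                             n_permitted=cfg.n_permitted, boost=cfg.clustered_boost,
                             n_families=cfg.n_families, n_orders=cfg.n_orders)
    traits, _ = simulate_traits(status, cfg.trait_effects,
                                intercept_sd=cfg.intercept_sd,
                                missing=cfg.missing_fraction, seed=s_traits,
                                regenerate_status=False)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "status": outdir / "status.csv",
        "traits": outdir / "traits.csv",
    }
    tree.write_newick(paths["tree"])
    status.data[["species", "family", "order", "appendix"]].to_csv(
        paths["status"], index=False)
    traits.write_csv(paths["traits"])
    return paths
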