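"""Synthetic-data generators: determinism, invariants, known structure."""

import numpy as np
import pandas as pd
import pytest

from invade.selectivity import selectivity_test
from invade.synthetic import (SyntheticConfig, assign_families,
                              make_default_fixture, simulate_status,
                              simulate_traits, simulate_tree)
from invade.tables import parse_status, parse_traits


def test_tree_shape_and_determinism():
    t1 = simulate_tree(50, "yule", seed=0)
    t2 = simulate_tree(50, "yule", seed=0)
    assert t1.n_tips == 50
    assert len(t1._nodes) == 99  # binary: n tips + n-1 internal nodes
    assert t1.write_newick() == t2.write_newick()
    assert simulate_tree(50, "yule", seed=1).write_newick() != t1.write_newick()
    with pytest.raises(ValueError):
        simulate_tree(2, "yule", seed=0)


@pytest.mark.parametrize("n", [10, 64])
def test_yule_trees_are_ultrametric(n):
    tree = simulate_tree(n, "yule", seed=3, depth=100.0)
    depths = [leaf.distance_from_root()
              for leaf in tree.dendropy_tree.leaf_node_iter()]
    assert np.ptp(depths) < 1e-9 * 100.0
    assert max(depths) == pytest.approx(100.0)


def test_families_are_monophyletic_contiguous_clades():
    tree = simulate_tree(77, "yule", seed=4)
    fams = assign_families(tree, 20, 9)
    assert fams["family"].nunique() == 20
    assert fams["order"].nunique() == 9
    assert set(fams.index) == set(tree.tip_names)
    # each family's tips form a clade: their MRCA contains no other tips
    dtree = tree.dendropy_tree
    for fam, members in fams.groupby("family").groups.items():
        taxa = [t for t in dtree.taxon_namespace if t.label in set(members)]
        mrca = dtree.mrca(taxa=taxa)
        assert len(mrca.leaf_nodes()) == len(members)


def test_status_prevalence_exact_in_every_mode():
    tree = simulate_tree(60, "yule", seed=5)
    for mode in ("random", "bm_threshold", "taxon_clustered"):
        status = simulate_status(tree, mode, prevalence=17, seed=6)
        assert int(status.data["y"].sum()) == 17
        assert len(status.data) == 60
    with pytest.raises(ValueError):
        simulate_status(tree, "random", prevalence=60, seed=6)


def test_status_tables_satisfy_parser_invariants():
    """Generated tables round-trip through the parser unchanged."""
    tree = simulate_tree(40, "yule", seed=7)
    status = simulate_status(tree, "taxon_clustered", prevalence=10, seed=8,
                             n_permitted=4)
    reparsed = parse_status(status.data[["species", "family", "order",
                                         "appendix"]])
    pd.testing.assert_frame_equal(reparsed.data, status.data)
    assert status.counts()["permitted"] == 4


def test_taxon_clustered_mode_enriches_boosted_family():
    """With a large boost the designated family is flagged 'over' by the
    selectivity test far more often than chance."""
    hits = 0
    for rep in range(20):
        tree = simulate_tree(77, "yule", seed=100 + rep)
        status = simulate_status(tree, "taxon_clustered", prevalence=19,
                                 seed=rep, boost=10.0)
        out = selectivity_test(status, "family", n_reps=300, seed=rep)
        big_fam = status.data["family"].value_counts().index[0]
        hits += (out.set_index("taxon").loc[big_fam, "verdict"] == "over")
    assert hits >= 10


def test_traits_missingness_rate_and_determinism(tmp_path):
    tree = simulate_tree(100, "yule", seed=9)
    status = simulate_status(tree, "random", prevalence=30, seed=10)
    traits, _ = simulate_traits(status, {"t1": 0.5, "t2": 0.0}, missing=0.2,
                                seed=11)
    frac = traits.data.isna().to_numpy().mean()
    assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / traits.data.size)
    # same seed -> byte-identical CSV
    t2, _ = simulate_traits(status, {"t1": 0.5, "t2": 0.0}, missing=0.2, seed=11)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    traits.write_csv(p1)
    t2.write_csv(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_trait_effects_are_recoverable_truth():
    tree = simulate_tree(200, "yule", seed=12)
    status = simulate_status(tree, "random", prevalence=60, seed=13)
    traits, status2 = simulate_traits(status, {"real": 1.0, "noise": 0.0},
                                      intercept_sd=0.5, seed=14)
    joined = status2.data.set_index("species").join(traits.data)
    # logistic association present for 'real', absent for 'noise'
    r_real = np.corrcoef(joined["real"], joined["y"])[0, 1]
    r_noise = np.corrcoef(joined["noise"], joined["y"])[0, 1]
    assert r_real > 0.15
    assert abs(r_noise) < 0.15


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(n_species=10, prevalence=10)
    with pytest.raises(ValueError):
        SyntheticConfig(missing_fraction=1.0)


def test_default_fixture_shape(fixture_paths):
    status = parse_status(fixture_paths["status"])
    assert len(status.data) == 77
    assert status.counts() == {"invasive": 51, "prohibited": 19, "permitted": 7}
    assert status.data["family"].nunique() == 20
    assert status.data["order"].nunique() == 9
    traits = parse_traits(fixture_paths["traits"])
    assert traits.data.shape[0] == 77
    assert len(traits.traits) == 6


def test_bundled_fixture_matches_generator(fixture_paths):
    """The files shipped in the package are exactly the generator's output
    at the default seed."""
    from importlib.resources import files

    bundled = files("invade") / "fixtures"
    for name, path in fixture_paths.items():
        assert (bundled / path.name).read_bytes() == path.read_bytes()
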