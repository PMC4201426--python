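"""Tree I/O, terminal branch lengths, fair-proportion ED, cophenetic distances."""

import dendropy
import numpy as np
import pytest

from invade.phylo import Phylogeny, normalize_name, read_newick
from invade.synthetic import simulate_tree


def test_read_newick_basic(three_tip_tree):
    assert sorted(three_tip_tree.tip_names) == ["A", "B", "C"]
    assert three_tip_tree.n_tips == 3
    assert three_tip_tree.total_length == pytest.approx(5.0)


def test_read_newick_malformed():
    with pytest.raises(ValueError, match="malformed"):
        read_newick("((A:1,B:1:1,C:2);")


def test_name_normalization_unifies_spaces_and_underscores():
    assert normalize_name("Sus scrofa") == normalize_name("Sus_scrofa") == "Sus_scrofa"
    tree = read_newick("(('Sus scrofa':1,B:1):1,C:2);")
    assert "Sus_scrofa" in tree.tip_names


def test_duplicate_tips_after_normalization_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        read_newick("(('Sus scrofa':1,Sus_scrofa:1):1,C:2);")


def test_negative_branch_length_rejected():
    with pytest.raises(ValueError, match="finite and >= 0"):
        read_newick("((A:1,B:-0.5):1,C:2);")


def test_missing_branch_length_errors_unless_default_given():
    with pytest.raises(ValueError, match="missing branch length"):
        read_newick("((A:1,B):1,C:2);")
    tree = read_newick("((A:1,B):1,C:2);", default_edge_length=0.0)
    assert tree.terminal_branch_lengths()["B"] == 0.0


def test_terminal_branch_lengths_example(three_tip_tree):
    assert three_tip_tree.terminal_branch_lengths() == {"A": 1.0, "B": 1.0, "C": 2.0}


def test_terminal_branch_lengths_match_edge_walk_oracle():
    """BL equals a second, independent traversal over dendropy edges."""
    tree = simulate_tree(100, "yule", seed=5)
    oracle = {
        leaf.taxon.label: leaf.edge.length
        for leaf in tree.dendropy_tree.leaf_node_iter()
    }
    assert tree.terminal_branch_lengths() == pytest.approx(oracle)


def test_fair_proportion_worked_example(three_tip_tree):
    ed = three_tip_tree.fair_proportion_ed()
    assert ed == pytest.approx({"A": 1.5, "B": 1.5, "C": 2.0})


def test_fair_proportion_star_tree_equals_pendant_length():
    tree = read_newick("(A:2.5,B:2.5,C:2.5,D:2.5);")
    ed = tree.fair_proportion_ed()
    bl = tree.terminal_branch_lengths()
    assert ed == pytest.approx(bl)


@pytest.mark.parametrize("seed,n,model", [(0, 10, "yule"), (1, 50, "yule"),
                                          (2, 50, "coalescent"), (3, 137, "yule")])
def test_fair_proportion_conservation(seed, n, model):
    """sum of ED over tips equals total tree branch length exactly."""
    tree = simulate_tree(n, model, seed=seed)
    total = sum(tree.fair_proportion_ed().values())
    assert total == pytest.approx(tree.total_length, rel=1e-12)


def test_fair_proportion_matches_per_edge_accumulation_oracle():
    """Independent oracle: walk every edge, split its length over the tips
    below it, and accumulate per tip."""
    tree = simulate_tree(50, "yule", seed=11)
    oracle = {t: 0.0 for t in tree.tip_names}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips_below = [lf.taxon.label for lf in node.leaf_iter()]
        share = node.edge.length / len(tips_below)
        for t in tips_below:
            oracle[t] += share
    assert tree.fair_proportion_ed() == pytest.approx(oracle)


def test_cophenetic_worked_example(three_tip_tree):
    d = three_tip_tree.cophenetic_matrix()
    assert d.loc["A", "B"] == pytest.approx(2.0)
    assert d.loc["A", "C"] == pytest.approx(4.0)
    assert d.loc["B", "C"] == pytest.approx(4.0)
    assert np.allclose(d.to_numpy(), d.to_numpy().T)
    assert np.allclose(np.diag(d.to_numpy()), 0.0)


def test_cophenetic_matches_dendropy_patristic_oracle():
    tree = simulate_tree(30, "coalescent", seed=7)
    ours = tree.cophenetic_matrix()
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    for i, a in enumerate(tree.tip_names):
        for b in tree.tip_names[i + 1:]:
            assert ours.loc[a, b] == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9)


def test_cophenetic_four_point_condition():
    """On an additive tree, of the three pairwise-sum combinations for any
    four tips, the two largest are equal."""
    tree = simulate_tree(12, "yule", seed=3)
    d = tree.cophenetic_matrix()
    names = tree.tip_names
    rng = np.random.default_rng(0)
    for _ in range(20):
        i, j, k, l = rng.choice(len(names), size=4, replace=False)
        a, b, c, e = (names[x] for x in (i, j, k, l))
        sums = sorted([d.loc[a, b] + d.loc[c, e],
                       d.loc[a, c] + d.loc[b, e],
                       d.loc[a, e] + d.loc[b, c]])
        assert sums[1] == pytest.approx(sums[2], rel=1e-9)


def test_newick_round_trip():
    tree = simulate_tree(25, "yule", seed=9)
    back = read_newick(tree.write_newick())
    assert sorted(back.tip_names) == sorted(tree.tip_names)
    assert back.total_length == pytest.approx(tree.total_length, rel=1e-6)
    assert back.terminal_branch_lengths() == pytest.approx(
        tree.terminal_branch_lengths(), rel=1e-6)
    d1 = tree.cophenetic_matrix()
    d2 = back.cophenetic_matrix().loc[d1.index, d1.columns]
    assert np.allclose(d1.to_numpy(), d2.to_numpy(), rtol=1e-6)


def test_restrict_to_prunes_tree(three_tip_tree):
    sub = three_tip_tree.restrict_to(["A", "C"])
    assert sorted(sub.tip_names) == ["A", "C"]
    with pytest.raises(ValueError):
        three_tip_tree.restrict_to(["A"])


def test_polytomy_accepted_in_core_metrics():
    tree = read_newick("((A:1,B:1,C:1):1,D:2);")
    assert not tree.is_bifurcating()
    ed = tree.fair_proportion_ed()
    assert sum(ed.values()) == pytest.approx(tree.total_length)
    resolved = tree.resolve_polytomies(seed=0)
    assert resolved.is_bifurcating()
    assert resolved.total_length == pytest.approx(tree.total_length)
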