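import numpy as np
import pytest

from phylohgt.experiments import (
    mad_grid_oracle,
    random_ultrametric_tree,
    random_unrooted_tree,
)
from phylohgt.rooting import mad_root, pairwise_distances
from phylohgt.trees import GeneTree


def test_pairwise_distances_path_sums():
    gt = GeneTree.from_newick("((A:1,B:1):1,C:2);")
    d = pairwise_distances(gt)
    assert d.loc["A", "B"] == pytest.approx(2)
    assert d.loc["A", "C"] == pytest.approx(4)
    assert d.loc["B", "C"] == pytest.approx(4)
    assert (np.diag(d.values) == 0).all()


def test_pairwise_distances_star():
    gt = GeneTree.from_newick("(A:1,B:1,C:1);")
    d = pairwise_distances(gt)
    off = d.values[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 2.0)


def test_pairwise_distances_matches_naive_walk():
    rng = np.random.default_rng(7)
    gt = random_unrooted_tree(10, rng)
    d = pairwise_distances(gt)
    tree = gt.tree
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}

    def naive(a, b):
        anc, acc, x = {}, 0.0, leaves[a]
        while x is not None:
            anc[id(x)] = acc
            acc += x.edge.length or 0.0
            x = x.parent_node
        acc, x = 0.0, leaves[b]
        while id(x) not in anc:
            acc += x.edge.length or 0.0
            x = x.parent_node
        return acc + anc[id(x)]

    for a in d.index:
        for b in d.columns:
            if a < b:
                assert d.loc[a, b] == pytest.approx(naive(a, b), abs=1e-12)


def test_mad_clock_caterpillar():
    """On ((A:1,B:1):1,C:2) every leaf is 2 from the internal node by C,
    so the root lands there with zero deviation."""
    res = mad_root(GeneTree.from_newick("((A:1,B:1):1,C:2);"))
    assert res.mad_score == pytest.approx(0.0, abs=1e-12)
    assert res.root_bipartition == frozenset(
        {frozenset({"A", "B"}), frozenset({"C"})}
    )


def test_mad_two_cherry_midpoint():
    res = mad_root(GeneTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);"))
    assert res.mad_score == pytest.approx(0.0, abs=1e-12)
    assert res.root_bipartition == frozenset(
        {frozenset({"A", "B"}), frozenset({"C", "D"})}
    )
    assert res.rho == pytest.approx(0.5, abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_mad_matches_grid_oracle(seed):
    """Closed-form rho and branch choice agree with an exhaustive
    branch x rho-grid scan using independently computed path distances."""
    rng = np.random.default_rng(seed)
    gt = random_unrooted_tree(10, rng)
    res = mad_root(gt)
    score, split, rho = mad_grid_oracle(gt)
    assert split == res.root_bipartition
    assert res.mad_score == pytest.approx(score, abs=1e-6)
    assert res.rho == pytest.approx(rho, abs=2e-4)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_mad_recovers_clock_root(seed):
    rng = np.random.default_rng(seed)
    gt, true_split = random_ultrametric_tree(12, rng)
    res = mad_root(gt)
    assert res.root_bipartition == true_split
    assert res.mad_score <= 1e-10


def test_mad_scale_invariance():
    rng = np.random.default_rng(21)
    gt = random_unrooted_tree(8, rng)
    res1 = mad_root(gt)
    scaled = gt.copy()
    for e in scaled.tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= 7.5
    res2 = mad_root(scaled)
    assert res2.root_bipartition == res1.root_bipartition
    assert res2.mad_score == pytest.approx(res1.mad_score, rel=1e-9)
    assert res2.rho == pytest.approx(res1.rho, abs=1e-9)


def test_mad_child_order_invariance():
    a = GeneTree.from_newick("((A:1.1,B:0.7):0.5,(C:1.3,D:0.2):0.9,E:2.0);")
    b = GeneTree.from_newick("(E:2.0,(D:0.2,C:1.3):0.9,(B:0.7,A:1.1):0.5);")
    ra, rb = mad_root(a), mad_root(b)
    assert ra.root_bipartition == rb.root_bipartition
    assert ra.mad_score == pytest.approx(rb.mad_score, abs=1e-12)
    assert ra.rho == pytest.approx(rb.rho, abs=1e-12)


def test_mad_preserves_supports_on_bipartitions():
    gt = GeneTree.from_newick("((A:1,B:1)95:1,(C:1,D:1)88:1,E:3);")
    res = mad_root(gt)
    rooted = res.rooted_tree.tree
    found = {}
    for node in rooted.preorder_internal_node_iter():
        if node is rooted.seed_node or node.label is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        found[leaves] = node.label
    assert found.get(frozenset({"A", "B"})) == "95"
    assert found.get(frozenset({"C", "D"})) == "88"


def test_mad_errors():
    with pytest.raises(ValueError, match="3 leaves"):
        mad_root(GeneTree.from_newick("(A:1,B:1);"))
    with pytest.raises(ValueError, match="zero"):
        mad_root(GeneTree.from_newick("((A:0,B:0):0,C:0);"))


def test_zero_distance_pair_warns():
    gt = GeneTree.from_newick("((A:0,B:0):1,C:1,D:2);")
    with pytest.warns(UserWarning, match="zero path distance"):
        mad_root(gt)
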