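"""Minimal ancestor deviation (MAD) rooting.

An unrooted gene tree is rooted at the point that makes the tree look most
clock-like without assuming a clock: for every candidate position, each leaf
pair (b, c) induces an ancestor (the point of their connecting path closest
to the candidate root) and a relative deviation

    r_bc = | 2 * d(ancestor, b) / d(b, c) - 1 |,

zero when the ancestor sits exactly at the path midpoint.  The root is the
point minimizing the root-mean-square of r_bc over all leaf pairs.  Along a
branch of length L the optimal position rho has a closed form: for the pairs
whose path crosses the branch,

    rho* = sum (d_bc - 2 d_ib) / d_bc^2  /  ( 2 L * sum 1 / d_bc^2 ),

clamped to [0, 1], where d_ib is the distance from the branch's proximal
endpoint to leaf b; pairs on one side of the branch contribute a
rho-independent deviation.  On an ultrametric tree the true root branch
scores exactly zero.

Deviations are invariant to a global rescaling of branch lengths, and the
choice of root is invariant to leaf relabelling and child order (ties between
equal-scoring branches are broken by the lexicographically smallest leaf
bipartition).  Leaf pairs at zero path distance (identical sequences) carry
no midpoint information and are skipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .trees import GeneTree

_TIE_TOL = 1e-12


@dataclass
class RootingResult:
    rooted_tree: GeneTree
    root_bipartition: frozenset[frozenset[str]]
    rho: float
    mad_score: float
    ambiguity_index: float


def _distance_arrays(tree: dendropy.Tree):
    """Per-node distances to every leaf, plus each node's below-leaf mask."""
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    n = len(leaves)
    index = {id(l): i for i, l in enumerate(leaves)}
    below: dict[int, np.ndarray] = {}
    dist: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            m = np.zeros(n, dtype=bool)
            m[index[id(node)]] = True
            below[id(node)] = m
            dist[id(node)] = np.zeros(n)
        else:
            m = np.zeros(n, dtype=bool)
            d = np.zeros(n)
            for child in node.child_nodes():
                length = child.edge.length
                if length is None:
                    raise ValueError("tree has a branch without a length")
                cm = below[id(child)]
                m |= cm
                d[cm] = dist[id(child)][cm] + length
            below[id(node)] = m
            dist[id(node)] = d
    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        m = below[id(node)]
        dist[id(node)][~m] = dist[id(node.parent_node)][~m] + node.edge.length
    return leaves, below, dist


def pairwise_distances(gt: GeneTree) -> pd.DataFrame:
    """Symmetric leaf-by-leaf path-length matrix (labels sorted)."""
    leaves, _, dist = _distance_arrays(gt.tree)
    labels = [l.taxon.label for l in leaves]
    rows = np.stack([dist[id(l)] for l in leaves])
    return pd.DataFrame(rows, index=labels, columns=labels)


def _same_side_ss(vals: np.ndarray, mask: np.ndarray, dl: np.ndarray) -> tuple[float, int]:
    """Sum of squared deviations for leaf pairs on one side of a branch."""
    k = int(mask.sum())
    if k < 2:
        return 0.0, 0
    v = vals[mask]
    sub = dl[np.ix_(mask, mask)]
    iu = np.triu_indices(k, k=1)
    d = sub[iu]
    diff = np.abs(v[:, None] - v[None, :])[iu]
    valid = d > 0
    r = diff[valid] / d[valid]
    return float((r * r).sum()), int(valid.sum())


def _edge_score(length, x, y, mask, dl):
    """(score_sumsq, n_pairs, rho) for one candidate branch."""
    a = ~mask
    sub = dl[np.ix_(mask, a)]
    valid = sub > 0
    inv = np.where(valid, 1.0 / np.where(valid, sub, 1.0), 0.0)
    xm = x[mask][:, None]
    inv2 = inv * inv
    den = 2.0 * length * inv2.sum()
    if den > 0:
        rho = float(((sub - 2.0 * xm) * inv2)[valid].sum() / den)
        rho = min(max(rho, 0.0), 1.0)
    else:
        rho = 0.0
    r_cross = (2.0 * (rho * length + xm) * inv - 1.0)[valid]
    ss = float((r_cross * r_cross).sum())
    n_pairs = int(valid.sum())
    ss_b, n_b = _same_side_ss(x, mask, dl)
    ss_a, n_a = _same_side_ss(y, a, dl)
    return ss + ss_b + ss_a, n_pairs + n_b + n_a, rho


def _canonical_key(labels_below: tuple[str, ...], labels_above: tuple[str, ...]):
    return min(labels_below, labels_above)


def mad_root(gt: GeneTree) -> RootingResult:
    """Root a gene tree by minimal ancestor deviation.

    The input must be unrooted (basal multifurcation) with at least three
    leaves and a positive total branch length.  The output is a rooted copy
    with a new degree-2 root node; support labels are re-attached to the same
    leaf bipartitions, and the support of the branch that was split is copied
    to both daughter root edges.
    """
    work = gt.copy()
    tree = work.tree
    if work.rooted:
        tree.deroot()
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if n_leaves < 3:
        raise ValueError("MAD rooting needs at least 3 leaves")
    total_length = sum(
        e.length or 0.0 for e in tree.preorder_edge_iter() if e.length is not None
    )
    if total_length <= 0:
        raise ValueError("cannot root a tree whose total branch length is zero")

    leaves, below, dist = _distance_arrays(tree)
    labels = [l.taxon.label for l in leaves]
    label_arr = np.asarray(labels, dtype=object)
    dl = np.stack([dist[id(l)] for l in leaves])
    if np.any((dl == 0) & ~np.eye(len(labels), dtype=bool)):
        warnings.warn(
            "tree contains leaf pairs at zero path distance; "
            "those pairs are skipped by MAD",
            stacklevel=2,
        )

    root = tree.seed_node
    records = []  # (score, canonical_key, node, rho, below_labels)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        mask = below[id(node)]
        ss, n_pairs, rho = _edge_score(
            node.edge.length, dist[id(node)], dist[id(node.parent_node)], mask, dl
        )
        if n_pairs == 0:
            continue
        score = float(np.sqrt(ss / n_pairs))
        below_lab = tuple(sorted(label_arr[mask]))
        above_lab = tuple(sorted(label_arr[~mask]))
        records.append((score, _canonical_key(below_lab, above_lab), node, rho, below_lab))

    records.sort(key=lambda r: r[0])
    best_score = records[0][0]
    candidates = [r for r in records if r[0] <= best_score + _TIE_TOL]
    candidates.sort(key=lambda r: r[1])
    score, _, node, rho, below_lab = candidates[0]
    second = next((r[0] for r in records if r[2] is not node), None)
    if second is None or second == 0.0:
        ambiguity = 1.0
    else:
        ambiguity = best_score / second

    # Record supports by unrooted bipartition before the topology changes.
    support_by_split: dict[tuple[str, ...], str] = {}
    for inner in tree.preorder_internal_node_iter():
        if inner is root or inner.label is None:
            continue
        b = tuple(sorted(label_arr[below[id(inner)]]))
        a = tuple(sorted(label_arr[~below[id(inner)]]))
        support_by_split[_canonical_key(b, a)] = inner.label

    length = node.edge.length
    tree.reroot_at_edge(node.edge, length1=(1.0 - rho) * length, length2=rho * length)
    tree.seed_node.label = None

    # Re-attach supports to the same bipartitions in the rooted tree.  The two
    # root edges share the split branch's bipartition and both receive its
    # support.
    all_labels = frozenset(labels)
    below_sets: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below_sets[id(nd)] = frozenset([nd.taxon.label])
        else:
            acc: frozenset[str] = frozenset()
            for ch in nd.child_nodes():
                acc |= below_sets[id(ch)]
            below_sets[id(nd)] = acc
    for nd in tree.preorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        b = tuple(sorted(below_sets[id(nd)]))
        a = tuple(sorted(all_labels - below_sets[id(nd)]))
        nd.label = support_by_split.get(_canonical_key(b, a))

    work.rooted = True
    bipart = frozenset({frozenset(below_lab), all_labels - frozenset(below_lab)})
    # Report rho from the endpoint on the side holding the smallest leaf label.
    rho_report = rho if min(labels) in set(below_lab) else 1.0 - rho
    return RootingResult(
        rooted_tree=work,
        root_bipartition=bipart,
        rho=rho_report,
        mad_score=score,
        ambiguity_index=ambiguity,
    )
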