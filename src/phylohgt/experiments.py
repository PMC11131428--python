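"""Calibration and validation experiments over the synthetic pipeline.

Each function runs one self-contained experiment - planted-transfer
round-trips, brute-force oracle comparisons for the MAD root and the
hypergeometric tail, screen-filter checks, a null-calibration of the
enrichment test, and the patchiness example - and returns plain numbers.
They are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt
from typing import Optional

import dendropy
import numpy as np

from .classify import (
    Category,
    DIRECTIONAL,
    FLAG_SINGLE_BACTERIUM,
    HGTCall,
    classify_tree,
)
from .enrichment import hypergeom_upper
from .recency import RecencyScore, score_recency
from .rooting import mad_root
from .screen import HomologHit, filter_hits
from .synthetic import (
    SimConfig,
    SimTruth,
    _random_ultrametric,
    clean_config,
    make_species_tree,
    simulate_gene_tree,
    simulate_hits,
    simulate_presence_matrix,
    taxon_map_for,
)
from .trees import GeneTree

# ---------------------------------------------------------------------------
# planted-transfer round trips


def simulate_and_classify(
    direction: Optional[Category], seed: int, **preset_overrides
) -> tuple[HGTCall, SimTruth]:
    """One gene tree through the full pipeline: simulate, MAD-root, classify."""
    cfg = clean_config(direction, seed, **preset_overrides)
    species = make_species_tree(cfg)
    gt, truth = simulate_gene_tree(species, cfg, gene_id=f"g{seed}")
    rooted = mad_root(gt).rooted_tree
    call = classify_tree(rooted, taxon_map_for(cfg), gene_id=f"g{seed}")
    return call, truth


def direction_recovery(n_per_condition: int, seed: int) -> dict:
    """Recovery of planted direction on clean transfers plus a no-HGT panel."""
    rng = np.random.default_rng(seed)
    out: dict = {"n_per_condition": n_per_condition}
    for key, direction in (
        ("b2p", Category.BACTERIA_TO_PLANTS),
        ("p2b", Category.PLANTS_TO_BACTERIA),
    ):
        correct = 0
        for _ in range(n_per_condition):
            call, _ = simulate_and_classify(direction, int(rng.integers(0, 2**31 - 1)))
            correct += call.category is direction
        out[f"{key}_correct"] = correct
        out[f"{key}_pct"] = 100.0 * correct / n_per_condition
    directional = 0
    for _ in range(n_per_condition):
        call, _ = simulate_and_classify(None, int(rng.integers(0, 2**31 - 1)))
        directional += call.category in DIRECTIONAL
    out["no_hgt_directional_calls"] = directional
    return out


def single_bacterium_exclusion(n_total: int, seed: int) -> dict:
    """Transfers touching exactly one bacterial genome must be set aside."""
    rng = np.random.default_rng(seed)
    flagged = directional = 0
    for i in range(n_total):
        if i % 2 == 0:
            call, _ = simulate_and_classify(
                Category.PLANTS_TO_BACTERIA,
                int(rng.integers(0, 2**31 - 1)),
                n_transferred=1,
            )
        else:
            call, _ = simulate_and_classify(
                Category.BACTERIA_TO_PLANTS,
                int(rng.integers(0, 2**31 - 1)),
                graft_depth=1,
            )
        flagged += FLAG_SINGLE_BACTERIUM in call.flags
        directional += call.category in DIRECTIONAL
    return {
        "n": n_total,
        "flagged": flagged,
        "flagged_pct": 100.0 * flagged / n_total,
        "directional_calls": directional,
    }


# ---------------------------------------------------------------------------
# MAD rooting vs brute-force grid oracle


def random_unrooted_tree(n_leaves: int, rng) -> GeneTree:
    """Random topology by sequential leaf attachment, exponential lengths."""
    t = dendropy.Tree.get(data="(L00:1,L01:1,L02:1);", schema="newick")
    for i in range(3, n_leaves):
        edges = [e for e in t.preorder_edge_iter() if e.head_node.parent_node is not None]
        e = edges[int(rng.integers(0, len(edges)))]
        head, tail = e.head_node, e.tail_node
        mid = dendropy.Node()
        tail.add_child(mid)
        tail.remove_child(head)
        mid.add_child(head)
        mid.edge.length = head.edge.length = (e.length or 1.0) / 2
        leaf = dendropy.Node()
        leaf.taxon = t.taxon_namespace.require_taxon(label=f"L{i:02d}")
        leaf.edge.length = 1.0
        mid.add_child(leaf)
    for e in t.preorder_edge_iter():
        if e.head_node.parent_node is not None:
            e.length = float(rng.exponential(1.0))
    return GeneTree.from_newick(t.as_string(schema="newick").strip())


def random_ultrametric_tree(n_leaves: int, rng) -> tuple[GeneTree, frozenset]:
    """Random clock tree and the bipartition of its true root branch."""
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    root = _random_ultrametric(labels, 1.0, rng)
    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tree.taxon_namespace.require_taxon(label=leaf.sim_label)
    children = tree.seed_node.child_nodes()
    side = frozenset(l.taxon.label for l in children[0].leaf_iter())
    true_split = frozenset({side, frozenset(labels) - side})
    gt = GeneTree.from_newick(tree.as_string(schema="newick").strip())
    gt.tree.deroot()
    gt.rooted = False
    return gt, true_split


def mad_grid_oracle(gt: GeneTree, step: float = 1e-4):
    """Exhaustive scan: every branch x a rho grid, naive path distances.

    Independent of the closed-form implementation: distances come from
    parent-pointer path walks and the deviation sum is evaluated on the grid.
    Returns (score, bipartition, rho-from-smallest-label-side).
    """
    work = gt.copy()
    tree = work.tree
    if work.rooted:
        tree.deroot()
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    all_labels = frozenset(l.taxon.label for l in leaves)
    min_label = min(all_labels)

    def path_dist(a, b):
        anc, d, x = {}, 0.0, a
        while x is not None:
            anc[id(x)] = d
            d += x.edge.length or 0.0
            x = x.parent_node
        d, x = 0.0, b
        while id(x) not in anc:
            d += x.edge.length or 0.0
            x = x.parent_node
        return d + anc[id(x)]

    rhos = np.arange(0.0, 1.0 + step, step)
    best = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length
        below_ids = {id(l) for l in node.leaf_iter()}
        ss = np.zeros_like(rhos)
        count = 0
        for b, c in itertools.combinations(leaves, 2):
            dbc = path_dist(b, c)
            if dbc == 0:
                continue
            b_in, c_in = id(b) in below_ids, id(c) in below_ids
            if b_in != c_in:
                dib = path_dist(node, b if b_in else c)
                r = np.abs(2.0 * (rhos * length + dib) / dbc - 1.0)
            else:
                gate = node if b_in else node.parent_node
                r = np.full_like(
                    rhos, abs(path_dist(gate, b) - path_dist(gate, c)) / dbc
                )
            ss += r * r
            count += 1
        scores = np.sqrt(ss / count)
        k = int(scores.argmin())
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if best is None or scores[k] < best[0]:
            rho = rhos[k] if min_label in below else 1.0 - rhos[k]
            best = (float(scores[k]), frozenset({below, all_labels - below}), float(rho))
    return best


def mad_oracle_agreement(n_random: int, n_clock: int, seed: int, n_leaves: int = 10) -> dict:
    """Closed-form MAD vs grid oracle, and clock-tree root recovery."""
    rng = np.random.default_rng(seed)
    branch_match = rho_match = 0
    for _ in range(n_random):
        gt = random_unrooted_tree(n_leaves, rng)
        res = mad_root(gt)
        o_score, o_split, o_rho = mad_grid_oracle(gt)
        branch_match += o_split == res.root_bipartition
        rho_match += (o_split == res.root_bipartition) and abs(o_rho - res.rho) <= 2e-4
    clock_ok = 0
    max_clock_score = 0.0
    for _ in range(n_clock):
        gt, true_split = random_ultrametric_tree(n_leaves, rng)
        res = mad_root(gt)
        clock_ok += res.root_bipartition == true_split and res.mad_score <= 1e-10
        max_clock_score = max(max_clock_score, res.mad_score)
    return {
        "n_random": n_random,
        "branch_match": branch_match,
        "rho_match": rho_match,
        "n_clock": n_clock,
        "clock_ok": clock_ok,
        "max_clock_score": max_clock_score,
        "agreement_pct": 100.0 * (branch_match + clock_ok) / (n_random + n_clock),
    }


# ---------------------------------------------------------------------------
# screen filter


def screen_survivors(seed: int, n_pass=12, n_fail_identity=20, n_fail_coverage=8) -> int:
    """Survivor count of the identity/coverage filter on a planted hit table."""
    df = simulate_hits(n_pass, n_fail_identity, n_fail_coverage, seed=seed)
    hits = [
        HomologHit(
            query_id=r.qseqid, subject_id=r.sseqid, pident=r.pident,
            qstart=r.qstart, qend=r.qend, sstart=r.sstart, send=r.send,
            qlen=r.qlen, slen=r.slen,
        )
        for r in df.itertuples(index=False)
    ]
    return len(filter_hits(hits))


# ---------------------------------------------------------------------------
# hypergeometric tail: exact-arithmetic oracle and null calibration


def hypergeom_exact(k: int, n: int, K: int, N: int) -> float:
    """Upper tail by exact integer-arithmetic summation (oracle)."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


def hypergeom_max_rel_err(n_max: int = 60) -> float:
    """Worst relative error of the log-space tail over all tuples N <= n_max."""
    worst = 0.0
    for N in range(1, n_max + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                for k in range(0, min(n, K) + 1):
                    p = hypergeom_upper(k, n, K, N)
                    exact = hypergeom_exact(k, n, K, N)
                    err = abs(p - exact) / exact
                    if err > worst:
                        worst = err
    return worst


#: Null-calibration design: one term of K genes in a background of N, study
#: sets of n drawn uniformly.  The tail is discrete, so the sizes are chosen
#: to put an achievable significance level just below the nominal 5%
#: (P(X >= 3) = 0.0494 here): study sets with 3+ term genes are the ones
#: significant at p < 0.05, making the nominal type-I rate meaningful.
NULL_DESIGN = {"N": 3000, "K": 50, "n": 50}


def null_type_one_fraction(n_reps: int, seed: int) -> dict:
    """Fraction of null study sets significant at p < 0.05, with MC s.e."""
    N, K, n = NULL_DESIGN["N"], NULL_DESIGN["K"], NULL_DESIGN["n"]
    rng = np.random.default_rng(seed)
    term = frozenset(rng.choice(N, size=K, replace=False).tolist())
    hits = 0
    for _ in range(n_reps):
        study = rng.choice(N, size=n, replace=False)
        k = sum(1 for g in study if g in term)
        if hypergeom_upper(int(k), n, K, N) < 0.05:
            hits += 1
    frac = hits / n_reps
    se = sqrt(frac * (1.0 - frac) / n_reps) if 0 < frac < 1 else sqrt(0.05 * 0.95 / n_reps)
    return {"fraction": frac, "se": se, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# recency


def genus_patchiness_example(seed: int) -> RecencyScore:
    """A gene in 22 of 25 genomes of one genus, absent elsewhere."""
    matrix = simulate_presence_matrix(
        [("patchy_gene", "genus", 22)], n_genera=6, genomes_per_genus=25, seed=seed
    )
    return score_recency(matrix, "patchy_gene")
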