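import dendropy
import numpy as np
import pytest

from phylohgt.classify import Category, clade_composition
from phylohgt.screen import ScreenConfig, filter_hits
from phylohgt.synthetic import (
    DEFAULT_COUNTS,
    HGTSpec,
    SimConfig,
    clean_config,
    make_species_tree,
    simulate_annotations,
    simulate_gene_tree,
    simulate_hits,
    taxon_map_for,
)
from phylohgt.taxa import BACTERIA, PLANTS, TaxonGroup, organism_of
from tests.test_screen import read_frame


def counts(**kw):
    base = {g: 0 for g in DEFAULT_COUNTS}
    for name, v in kw.items():
        base[TaxonGroup[name]] = v
    return base


def test_species_tree_deterministic():
    cfg = SimConfig(seed=1)
    assert make_species_tree(cfg).to_newick() == make_species_tree(cfg).to_newick()


def test_species_tree_structure_small():
    cfg = SimConfig(
        counts=counts(PA_BACTERIA=2, NPA_BACTERIA=2, ARCHAEA=2, VASCULAR_PLANT=2,
                      BRYOPHYTE=2, ALGA=2, SAR=2, AMORPHEA=2),
        seed=5,
    )
    gt = make_species_tree(cfg)
    assert gt.n_leaves() == 16
    tmap = taxon_map_for(cfg)
    plants = tmap.organisms_in(PLANTS)
    mrca = gt.tree.mrca(taxon_labels=sorted(plants))
    assert {l.taxon.label for l in mrca.leaf_iter()} == plants  # plants monophyletic


def test_species_tree_is_ultrametric():
    gt = make_species_tree(SimConfig(seed=2))
    depths = {}
    for leaf in gt.tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depths[leaf.taxon.label] = d
    vals = np.array(list(depths.values()))
    assert np.allclose(vals, vals[0], atol=1e-9)


def test_zero_plants_with_plant_transfer_is_error():
    cfg = SimConfig(
        counts=counts(PA_BACTERIA=5, NPA_BACTERIA=5),
        hgt=HGTSpec(direction=Category.BACTERIA_TO_PLANTS),
    )
    with pytest.raises(ValueError, match="plants"):
        make_species_tree(cfg)


def test_gene_tree_identity_case():
    """No noise, no loss, no transfer: gene tree topology equals the species
    tree topology (same bipartitions after relabelling)."""
    cfg = SimConfig(seed=9, branch_noise_sigma=0.0, loss_prob=0.0)
    species = make_species_tree(cfg)
    gt, truth = simulate_gene_tree(species, cfg, gene_id="g")
    assert not truth.has_hgt and not truth.deleted_organisms
    assert sorted(organism_of(l) for l in gt.leaf_labels()) == sorted(
        species.leaf_labels()
    )

    def splits(tree_gt, strip):
        out = set()
        labels = frozenset(
            organism_of(l) if strip else l for l in tree_gt.leaf_labels()
        )
        for node in tree_gt.tree.preorder_internal_node_iter():
            below = frozenset(
                organism_of(l.taxon.label) if strip else l.taxon.label
                for l in node.leaf_iter()
            )
            if 1 < len(below) < len(labels):
                out.add(frozenset({below, labels - below}))
        return out

    assert splits(gt, strip=True) == splits(species, strip=False)


def test_gene_tree_planted_transfer_nests_acceptor():
    cfg = clean_config(Category.BACTERIA_TO_PLANTS, 3)
    species = make_species_tree(cfg)
    gt, truth = simulate_gene_tree(species, cfg, gene_id="g")
    assert truth.has_hgt and truth.direction == "BACTERIA_TO_PLANTS"
    tmap = taxon_map_for(cfg)
    from phylohgt.rooting import mad_root

    rooted = mad_root(gt).rooted_tree
    plants = [
        l for l in rooted.leaf_labels() if tmap.group_of(organism_of(l)) in PLANTS
    ]
    mrca = rooted.tree.mrca(taxon_labels=plants)
    sister_groups = set()
    for sib in mrca.parent_node.child_nodes():
        if sib is not mrca:
            sister_groups |= {
                tmap.group_of(organism_of(l.taxon.label)) for l in sib.leaf_iter()
            }
    assert sister_groups <= BACTERIA  # the plant clade's sister is bacterial


def test_gene_tree_loss_conservation():
    cfg = SimConfig(seed=13, branch_noise_sigma=0.0, loss_prob=0.2)
    species = make_species_tree(cfg)
    gt, truth = simulate_gene_tree(species, cfg, gene_id="g")
    survivors = {organism_of(l) for l in gt.leaf_labels()}
    deleted = {organism_of(l) for l in truth.deleted_organisms}
    assert survivors | deleted == set(species.leaf_labels())
    assert not survivors & deleted
    assert gt.n_leaves() >= 4


def test_gene_tree_deterministic_and_unrooted():
    cfg = clean_config(Category.PLANTS_TO_BACTERIA, 4)
    species = make_species_tree(cfg)
    a, _ = simulate_gene_tree(species, cfg, gene_id="g")
    b, _ = simulate_gene_tree(species, cfg, gene_id="g")
    assert a.to_newick() == b.to_newick()
    assert not a.rooted
    assert len(a.tree.seed_node.child_nodes()) >= 3


def test_gene_tree_supports_in_range():
    cfg = SimConfig(seed=6, support_true_range=(95, 100), loss_prob=0.0)
    species = make_species_tree(cfg)
    gt, _ = simulate_gene_tree(species, cfg, gene_id="g")
    supports = [
        int(n.label)
        for n in gt.tree.preorder_internal_node_iter()
        if n.label is not None
    ]
    assert supports and all(95 <= s <= 100 for s in supports)


def test_paralog_mode_duplicates_leaves():
    cfg = SimConfig(seed=8, paralog_prob=0.3, loss_prob=0.0)
    species = make_species_tree(cfg)
    gt, _ = simulate_gene_tree(species, cfg, gene_id="g7")
    labels = gt.leaf_labels()
    orgs = [organism_of(l) for l in labels]
    assert len(labels) > len(set(orgs))  # at least one organism twice
    comp = clade_composition(gt.tree.seed_node, taxon_map_for(cfg))
    assert comp.total == len(labels)
    assert sum(len(v) for v in comp.organisms.values()) == len(set(orgs))


def test_simulate_hits_exact_survivor_count():
    for seed in (0, 1, 2):
        df = simulate_hits(12, 20, 8, seed=seed)
        assert len(df) == 40
        assert len(filter_hits(read_frame(df), ScreenConfig())) == 12


def test_simulate_hits_avoids_boundary_bands():
    df = simulate_hits(40, 40, 40, seed=3)
    assert not ((df.pident >= 34.95) & (df.pident < 35.0)).any()
    qcov = (df.qend - df.qstart + 1) / df.qlen
    scov = (df.send - df.sstart + 1) / df.slen
    for cov in (qcov, scov):
        assert not ((cov > 0.799) & (cov < 0.801)).any()


def test_simulate_hits_all_fail():
    df = simulate_hits(0, 10, 10, seed=4)
    assert len(filter_hits(read_frame(df), ScreenConfig())) == 0


def test_simulate_annotations_planted_and_deterministic():
    u1, s1 = simulate_annotations(
        N=500, terms=[("T1", 20), ("T2", 30)], planted=("T1", 10, 16), seed=5
    )
    u2, s2 = simulate_annotations(
        N=500, terms=[("T1", 20), ("T2", 30)], planted=("T1", 10, 16), seed=5
    )
    assert s1 == s2 and u1.term_to_genes == u2.term_to_genes
    assert len(s1) == 16
    assert len(s1 & u1.term_to_genes["T1"]) == 10


def test_simulate_annotations_unsatisfiable():
    with pytest.raises(ValueError, match="unsatisfiable"):
        simulate_annotations(N=30, terms=[("T1", 5)], planted=("T1", 6, 10), seed=1)
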