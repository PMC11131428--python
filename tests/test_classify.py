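import pytest

from phylohgt.classify import (
    Category,
    ClassifyConfig,
    DIRECTIONAL,
    FLAG_LOW_BOOTSTRAP,
    FLAG_NO_BOOTSTRAP,
    FLAG_SINGLE_BACTERIUM,
    HGTCall,
    clade_composition,
    classify_tree,
    find_mixed_clades,
    normalize_support,
    pct_acquired_by_plants,
    summarize_calls,
)
from phylohgt.experiments import simulate_and_classify
from phylohgt.taxa import TaxonGroup
from phylohgt.trees import GeneTree

# mostly-bacterial tree with a plant cherry nested next to three PA bacteria
B2P_NEWICK = (
    "((Arch1|g:1,(((P1|g:1,P2|g:1)99:1,(B1|g:1,(B2|g:1,B3|g:1)97:1)96:1)98:1,"
    "(B4|g:1,N1|g:1)90:1)92:1)91:1,(B5|g:1,(B6|g:1,N2|g:1)89:1)88:1);"
)

# same shape but the plant cherry's only partner is one bacterium
SINGLE_BACT_NEWICK = (
    "((Arch1|g:1,(((P1|g:1,P2|g:1)99:1,B1|g:1)98:1,"
    "(B4|g:1,N1|g:1)90:1)92:1)91:1,(B5|g:1,(B6|g:1,N2|g:1)89:1)88:1);"
)

# mostly-eukaryotic tree; four bacteria nested among vascular plants
P2B_NEWICK = (
    "(A1|g:1,(Sar1|g:1,(Alga1|g:1,(Bryo1|g:1,(P1|g:1,"
    "((B1|g:1,(B2|g:1,(B3|g:1,N1|g:1)99:1)99:1)98:1,(P2|g:1,P3|g:1)96:1)94:1"
    ")93:1)92:1)91:1)90:1);"
)

# bacteria nested next to the alga, plants further out -> eukaryote donor side
E2B_NEWICK = (
    "(A1|g:1,(Sar1|g:1,((Bryo1|g:1,(P1|g:1,(P2|g:1,P3|g:1)95:1)95:1)95:1,"
    "((B1|g:1,(B2|g:1,B3|g:1)99:1)98:1,Alga1|g:1)94:1)93:1)92:1);"
)

# mostly-bacterial tree whose nested eukaryote clade mixes alga and plants
B2E_NEWICK = (
    "((Arch1|g:1,((B4|g:1,N1|g:1)90:1,((Alga1|g:1,(P1|g:1,P2|g:1)97:1)96:1,"
    "(B1|g:1,(B2|g:1,B3|g:1)95:1)94:1)98:1)92:1)91:1,"
    "(B5|g:1,(B6|g:1,N2|g:1)89:1)88:1);"
)

# the plant cherry's sister contains an Amorphea leaf: not HGT evidence
AMORPHEA_NEWICK = (
    "((Arch1|g:1,(((P1|g:1,P2|g:1)99:1,(B1|g:1,A1|g:1)96:1)98:1,"
    "(B4|g:1,N1|g:1)90:1)92:1)91:1,(B5|g:1,(B6|g:1,N2|g:1)89:1)88:1);"
)

VERTICAL_NEWICK = (
    "((Arch1|g:1,(B1|g:1,N1|g:1)99:1)98:1,(A1|g:1,(Sar1|g:1,(Alga1|g:1,"
    "(Bryo1|g:1,(P1|g:1,P2|g:1)95:1)95:1)95:1)95:1)97:1);"
)


@pytest.mark.parametrize(
    "raw,expected",
    [(0.99, 99.0), (1.0, 100.0), (85, 85.0), (0.0, 0.0), (None, None), ("", None)],
)
def test_normalize_support(raw, expected):
    assert normalize_support(raw) == expected


@pytest.mark.parametrize("raw", [-1, 101, -0.2])
def test_normalize_support_rejects_out_of_range(raw):
    with pytest.raises(ValueError):
        normalize_support(raw)


def test_clade_composition_counts_paralogs(small_map):
    gt = GeneTree.from_newick("((P1|g1:1,P1|g2:1)90:1,(B1|g1:1,N1|g1:1)90:1);")
    comp = clade_composition(gt.tree.seed_node, small_map)
    assert comp.leaves[TaxonGroup.VASCULAR_PLANT] == 2
    assert comp.organisms[TaxonGroup.VASCULAR_PLANT] == {"P1"}
    assert comp.leaf_count({TaxonGroup.PA_BACTERIA, TaxonGroup.NPA_BACTERIA}) == 2
    assert comp.total == 4


def test_find_mixed_clades_textbook(small_map):
    cands = find_mixed_clades(GeneTree.from_newick(B2P_NEWICK), small_map)
    leafsets = {frozenset(c.nested_leaves) for c in cands}
    assert frozenset({"P1|g", "P2|g"}) in leafsets
    # one node, both nested-partner readings at most
    assert len({id(c.node) for c in cands}) == 1


def test_find_mixed_clades_amorphea_veto(small_map):
    assert find_mixed_clades(GeneTree.from_newick(AMORPHEA_NEWICK), small_map) == []


def test_find_mixed_clades_all_bacterial(small_map):
    gt = GeneTree.from_newick("((B1|g:1,B2|g:1)90:1,(B3|g:1,N1|g:1)90:1);")
    assert find_mixed_clades(gt, small_map) == []


def test_classify_bacteria_to_plants(small_map):
    call = classify_tree(GeneTree.from_newick(B2P_NEWICK), small_map, gene_id="t")
    assert call.category is Category.BACTERIA_TO_PLANTS
    assert call.flags == set()
    assert call.key_support == 98
    assert call.n_bacterial_genomes == 3
    assert call.donor_group == "BACTERIA"
    assert call.acceptor_group == "PLANTS"
    assert call.pa_involvement == "PA"
    assert not call.ancient_in_plants  # P3 missing, no bryophyte/alga


def test_classify_single_bacterium_exclusion(small_map):
    call = classify_tree(GeneTree.from_newick(SINGLE_BACT_NEWICK), small_map)
    assert call.category is Category.UNCLEAR
    assert FLAG_SINGLE_BACTERIUM in call.flags


def test_classify_plants_to_bacteria(small_map):
    call = classify_tree(GeneTree.from_newick(P2B_NEWICK), small_map)
    assert call.category is Category.PLANTS_TO_BACTERIA
    assert call.n_bacterial_genomes == 4
    assert call.pa_involvement == "MIXED"
    assert call.donor_group == "PLANTS"
    assert call.acceptor_group == "BACTERIA"
    # all three vascular plants plus bryophyte and alga leaves present
    assert call.ancient_in_plants


def test_classify_eukaryotes_to_bacteria(small_map):
    call = classify_tree(GeneTree.from_newick(E2B_NEWICK), small_map)
    assert call.category is Category.EUKARYOTES_TO_BACTERIA


def test_classify_bacteria_to_eukaryotes(small_map):
    call = classify_tree(GeneTree.from_newick(B2E_NEWICK), small_map)
    assert call.category is Category.BACTERIA_TO_EUKARYOTES


def test_classify_vertical_tree_is_no_hgt(small_map):
    call = classify_tree(GeneTree.from_newick(VERTICAL_NEWICK), small_map)
    assert call.category is Category.NO_HGT


def test_classify_amorphea_in_mixed_branch_is_no_hgt(small_map):
    call = classify_tree(GeneTree.from_newick(AMORPHEA_NEWICK), small_map)
    assert call.category is Category.NO_HGT


def test_fractional_support_scale_flags_low_bootstrap(small_map):
    newick = B2P_NEWICK
    for raw in ("99", "98", "97", "96", "92", "91", "90", "89", "88"):
        newick = newick.replace(f"){raw}:", f")0.{raw}:")
    newick = newick.replace(")0.98:", ")0.75:", 1)
    call = classify_tree(GeneTree.from_newick(newick), small_map)
    assert call.category is Category.BACTERIA_TO_PLANTS
    assert call.key_support == 75
    assert FLAG_LOW_BOOTSTRAP in call.flags


def test_missing_support_flags_no_bootstrap(small_map):
    import re

    newick = re.sub(r"\)\d+:", "):", B2P_NEWICK)
    call = classify_tree(GeneTree.from_newick(newick), small_map)
    assert FLAG_NO_BOOTSTRAP in call.flags


def test_lowering_threshold_never_adds_flags(small_map):
    gt = GeneTree.from_newick(B2P_NEWICK.replace(")98:", ")75:", 1))
    flags = {}
    for th in (95, 80, 70):
        call = classify_tree(gt, small_map, ClassifyConfig(support_threshold=th))
        flags[th] = FLAG_LOW_BOOTSTRAP in call.flags
    assert flags[95] and flags[80] and not flags[70]


def test_unrooted_tree_rejected_with_remedy(small_map):
    gt = GeneTree.from_newick("(P1|g:1,P2|g:1,B1|g:1,B2|g:1);")
    with pytest.raises(ValueError, match="mad_root"):
        classify_tree(gt, small_map)


def test_classify_is_leaf_order_invariant(small_map):
    reordered = (
        "((B5|g:1,(N2|g:1,B6|g:1)89:1)88:1,(Arch1|g:1,((N1|g:1,B4|g:1)90:1,"
        "((B1|g:1,(B3|g:1,B2|g:1)97:1)96:1,(P2|g:1,P1|g:1)99:1)98:1)92:1)91:1);"
    )
    a = classify_tree(GeneTree.from_newick(B2P_NEWICK), small_map)
    b = classify_tree(GeneTree.from_newick(reordered), small_map)
    assert a.category is b.category
    assert a.mixed_clade == b.mixed_clade
    assert a.key_support == b.key_support
    assert a.flags == b.flags


@pytest.mark.parametrize(
    "counts,expected", [((59, 16), 79), ((1, 1), 50), ((0, 0), "NA"), ((2, 1), 67)]
)
def test_pct_acquired_by_plants(counts, expected):
    assert pct_acquired_by_plants(counts) == expected


def test_summarize_calls_table():
    calls = [
        HGTCall(gene_id=f"a{i}", category=Category.BACTERIA_TO_PLANTS)
        for i in range(3)
    ] + [HGTCall(gene_id="b", category=Category.PLANTS_TO_BACTERIA)]
    table = summarize_calls(calls).set_index("metric")["value"]
    assert table["category:BACTERIA_TO_PLANTS"] == 3
    assert table["category:PLANTS_TO_BACTERIA"] == 1
    assert table["pct_acquired_by_plants"] == 75


@pytest.mark.parametrize(
    "direction",
    [
        Category.BACTERIA_TO_PLANTS,
        Category.PLANTS_TO_BACTERIA,
        Category.BACTERIA_TO_EUKARYOTES,
        Category.EUKARYOTES_TO_BACTERIA,
    ],
)
def test_round_trip_recovers_planted_direction(direction):
    """Clean planted transfers come back with the planted category, and
    directional calls never rest on fewer than two bacterial genomes."""
    for seed in range(8):
        call, truth = simulate_and_classify(direction, 1000 + seed)
        assert call.category is direction
        assert call.n_bacterial_genomes >= 2


def test_round_trip_no_hgt_panel():
    for seed in range(8):
        call, truth = simulate_and_classify(None, 2000 + seed)
        assert call.category not in DIRECTIONAL
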