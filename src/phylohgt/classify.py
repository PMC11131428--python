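"""Topology-based HGT calling on rooted gene trees.

A cross-kingdom transfer leaves a characteristic incongruence: a pure clade
of one partner (e.g. plants) nested inside the other partner's part of the
tree (e.g. bacteria).  The classifier automates the corresponding inspection
rules:

* find the minimal "mixed" clades containing both eukaryote and bacterial
  leaves in which one partner forms a pure subclade and the rest of the clade
  is purely the other partner;
* a tree that is mostly bacterial with a nested pure plant subclade is a
  transfer from bacteria to plants (to eukaryotes in general when the nested
  subclade includes non-plant eukaryote groups); a mostly-eukaryotic tree
  with a nested bacterial subclade surrounded exclusively by plants is a
  transfer from plants to bacteria, otherwise from eukaryotes to bacteria;
* transfers involving a single bacterial genome are set aside (possible
  contamination), and the support of the mixed clade's stem branch below the
  threshold (default 80 on the 0-100 ultrafast-bootstrap scale) earns a
  low-confidence flag without deleting the call;
* the donor domain is read from the closest sister clades of the mixed
  clade, walking rootward until one super-group dominates.

Amorphea (animals, fungi, amoeba) leaves inside a plant-bacteria mixed clade
veto the plant call: shared presence with animals or fungi points to vertical
inheritance, not plant HGT.  A mixed clade spanning the entire tree is
likewise no evidence: the two domains being sisters *is* the vertical
expectation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

import dendropy
import pandas as pd

from .taxa import (
    BACTERIA,
    EUKARYOTES,
    PLANTS,
    TaxonGroup,
    TaxonMap,
    organism_of,
)
from .trees import GeneTree


class Category(str, enum.Enum):
    BACTERIA_TO_PLANTS = "BACTERIA_TO_PLANTS"
    PLANTS_TO_BACTERIA = "PLANTS_TO_BACTERIA"
    BACTERIA_TO_EUKARYOTES = "BACTERIA_TO_EUKARYOTES"
    EUKARYOTES_TO_BACTERIA = "EUKARYOTES_TO_BACTERIA"
    UNCLEAR = "UNCLEAR"
    NO_HGT = "NO_HGT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


DIRECTIONAL = frozenset(
    {
        Category.BACTERIA_TO_PLANTS,
        Category.PLANTS_TO_BACTERIA,
        Category.BACTERIA_TO_EUKARYOTES,
        Category.EUKARYOTES_TO_BACTERIA,
    }
)

FLAG_LOW_BOOTSTRAP = "LOW_BOOTSTRAP"
FLAG_NO_BOOTSTRAP = "NO_BOOTSTRAP"
FLAG_SINGLE_BACTERIUM = "SINGLE_BACTERIUM"
FLAG_AMORPHEA = "ANIMAL_FUNGAL_CONTAMINANT_IN_CLADE"


@dataclass
class ClassifyConfig:
    support_threshold: float = 80.0
    majority_fraction: float = 0.5
    min_bacteria_genomes: int = 2
    max_intruders: int = 0
    ancient_plant_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.majority_fraction < 1):
            raise ValueError("majority_fraction must be in (0, 1)")
        if self.min_bacteria_genomes < 2:
            raise ValueError("min_bacteria_genomes must be >= 2")


@dataclass
class HGTCall:
    gene_id: str
    category: Category
    mixed_clade: frozenset[str] = frozenset()
    key_support: Optional[float] = None
    donor_group: Optional[str] = None
    acceptor_group: Optional[str] = None
    pa_involvement: str = "NONE"
    n_bacterial_genomes: int = 0
    flags: set[str] = field(default_factory=set)
    ancient_in_plants: bool = False


def normalize_support(raw) -> Optional[float]:
    """Bring a support value onto the 0-100 scale (values <= 1 are fractions)."""
    if raw is None or raw == "":
        return None
    value = float(raw)
    if value < 0 or value > 100:
        raise ValueError(f"support value {value} outside [0, 100]")
    return value * 100.0 if value <= 1.0 else value


@dataclass
class Composition:
    """Leaf and distinct-organism counts of a clade, per taxon group."""

    leaves: dict[TaxonGroup, int]
    organisms: dict[TaxonGroup, set[str]]

    @property
    def total(self) -> int:
        return sum(self.leaves.values())

    def leaf_count(self, groups) -> int:
        return sum(self.leaves.get(g, 0) for g in groups)

    def organism_set(self, groups) -> set[str]:
        out: set[str] = set()
        for g in groups:
            out |= self.organisms.get(g, set())
        return out

    def groups_present(self) -> set[TaxonGroup]:
        return {g for g, c in self.leaves.items() if c > 0}


def clade_composition(node: dendropy.Node, taxon_map: TaxonMap) -> Composition:
    leaves: dict[TaxonGroup, int] = {}
    organisms: dict[TaxonGroup, set[str]] = {}
    for leaf in node.leaf_iter():
        org = organism_of(leaf.taxon.label)
        group = taxon_map.group_of(org)
        leaves[group] = leaves.get(group, 0) + 1
        organisms.setdefault(group, set()).add(org)
    return Composition(leaves=leaves, organisms=organisms)


@dataclass
class MixedClade:
    node: dendropy.Node
    nested_partner: str                 # "EUKARYOTES" or "BACTERIA"
    nested_leaves: frozenset[str]       # leaves of the pure nested subclade
    composition: Composition
    size: int


def _pure_fraction_split(children_comps, children_nodes, inside, outside, max_intruders):
    """Children forming a pure `inside` subclade vs a pure `outside` rest.

    Returns (nested_children, ok): nested_children are the children whose
    leaves are (up to max_intruders) all in `inside`; ok requires at least one
    nested child, at least one remaining child, and the remaining children to
    be (up to max_intruders) all in `outside`.
    """
    nested, rest = [], []
    for node, comp in zip(children_nodes, children_comps):
        foreign = comp.total - comp.leaf_count(inside)
        if foreign <= max_intruders and comp.leaf_count(inside) > 0:
            nested.append((node, comp))
        else:
            rest.append((node, comp))
    if not nested or not rest:
        return [], False
    rest_total = sum(c.total for _, c in rest)
    rest_outside = sum(c.leaf_count(outside) for _, c in rest)
    if rest_total - rest_outside > max_intruders:
        return [], False
    return nested, True


def find_mixed_clades(
    gt: GeneTree, taxon_map: TaxonMap, cfg: Optional[ClassifyConfig] = None
) -> list[MixedClade]:
    """Minimal clades mixing eukaryote and bacterial leaves with nested purity.

    Only proper clades qualify (the root spans the whole tree and carries no
    nesting information).  When the nested pure subclade is plant-only, the
    clade must contain no Amorphea leaves.  Candidates are ordered by clade
    size ascending.
    """
    cfg = cfg or ClassifyConfig()
    tree = gt.tree
    comps: dict[int, Composition] = {}
    for node in tree.postorder_node_iter():
        comps[id(node)] = clade_composition(node, taxon_map)

    candidates: list[MixedClade] = []
    for node in tree.postorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        comp = comps[id(node)]
        n_euk = comp.leaf_count(EUKARYOTES)
        n_bact = comp.leaf_count(BACTERIA)
        if n_euk == 0 or n_bact == 0:
            continue
        children = node.child_nodes()
        ccomps = [comps[id(c)] for c in children]

        for inside, outside, partner in (
            (EUKARYOTES, BACTERIA, "EUKARYOTES"),
            (BACTERIA, EUKARYOTES, "BACTERIA"),
        ):
            nested, ok = _pure_fraction_split(
                ccomps, children, inside, outside, cfg.max_intruders
            )
            if not ok:
                continue
            nested_leaves = frozenset(
                leaf.taxon.label for n, _ in nested for leaf in n.leaf_iter()
            )
            nested_groups: set[TaxonGroup] = set()
            for _, c in nested:
                nested_groups |= c.groups_present()
            if partner == "EUKARYOTES":
                # plant-bacteria mixed branch must not include animals/fungi,
                # and an Amorphea-only subclade beside bacteria is the
                # vertical-descent signal, not transfer evidence
                if (nested_groups & EUKARYOTES) <= PLANTS and comp.leaf_count(
                    {TaxonGroup.AMORPHEA}
                ) > 0:
                    continue
                if nested_groups <= {TaxonGroup.AMORPHEA}:
                    continue
            else:
                # bacteria nested in an Amorphea-only context: same signal
                euk_groups_in_m = comp.groups_present() & EUKARYOTES
                if euk_groups_in_m <= {TaxonGroup.AMORPHEA}:
                    continue
            # both readings (nested eukaryotes vs nested bacteria) can hold for
            # the same node; record each and let the whole-tree majority rule
            # decide which one is coherent
            candidates.append(
                MixedClade(
                    node=node,
                    nested_partner=partner,
                    nested_leaves=nested_leaves,
                    composition=comp,
                    size=comp.total,
                )
            )

    # minimality: drop any candidate that strictly contains another candidate
    leafsets = [
        frozenset(l.taxon.label for l in c.node.leaf_iter()) for c in candidates
    ]
    minimal = []
    for i, cand in enumerate(candidates):
        if any(i != j and leafsets[j] < leafsets[i] for j in range(len(candidates))):
            continue
        minimal.append(cand)
    minimal.sort(key=lambda c: (c.size, tuple(sorted(c.nested_leaves))))
    return minimal


def _sister_leaves(node: dendropy.Node) -> list[str]:
    parent = node.parent_node
    if parent is None:
        return []
    out = []
    for sib in parent.child_nodes():
        if sib is node:
            continue
        out.extend(l.taxon.label for l in sib.leaf_iter())
    return out


def _donor_from_sisters(
    node: dendropy.Node, taxon_map: TaxonMap, majority: float
) -> Optional[str]:
    """Walk rootward from the mixed clade until one super-group dominates."""
    current = node
    while current.parent_node is not None:
        labels = _sister_leaves(current)
        if labels:
            groups = [taxon_map.group_of(organism_of(l)) for l in labels]
            n = len(groups)
            for name, members in (
                ("BACTERIA", BACTERIA),
                ("PLANTS", PLANTS),
                ("EUKARYOTES", EUKARYOTES),
            ):
                if sum(g in members for g in groups) / n >= majority:
                    return name
        current = current.parent_node
    return None


def _tentative_category(
    cand: MixedClade,
    tree_comp: Composition,
    taxon_map: TaxonMap,
    cfg: ClassifyConfig,
) -> Optional[Category]:
    total = tree_comp.total
    bact_fraction = tree_comp.leaf_count(BACTERIA) / total
    euk_fraction = tree_comp.leaf_count(EUKARYOTES) / total
    nested_groups = {
        taxon_map.group_of(organism_of(l)) for l in cand.nested_leaves
    }
    if cand.nested_partner == "EUKARYOTES":
        if bact_fraction < cfg.majority_fraction:
            return None
        if nested_groups & EUKARYOTES <= PLANTS:
            return Category.BACTERIA_TO_PLANTS
        return Category.BACTERIA_TO_EUKARYOTES
    # nested bacteria inside a predominantly eukaryotic tree
    if euk_fraction < cfg.majority_fraction:
        return None
    context = [
        l.taxon.label
        for l in cand.node.leaf_iter()
        if l.taxon.label not in cand.nested_leaves
    ]
    context.extend(_sister_leaves(cand.node))
    context_groups = {taxon_map.group_of(organism_of(l)) for l in context}
    if context_groups <= PLANTS:
        return Category.PLANTS_TO_BACTERIA
    return Category.EUKARYOTES_TO_BACTERIA


def classify_tree(
    gt: GeneTree,
    taxon_map: TaxonMap,
    cfg: Optional[ClassifyConfig] = None,
    gene_id: str = "",
) -> HGTCall:
    """Apply the decision procedure to one rooted, support-normalized tree."""
    cfg = cfg or ClassifyConfig()
    if not gt.rooted:
        raise ValueError(
            "classify_tree needs a rooted tree; run mad_root on the gene tree first"
        )
    tree_comp = clade_composition(gt.tree.seed_node, taxon_map)

    # ancientness: nearly all vascular plants of the panel, plus at least one
    # bryophyte or alga leaf
    vasc_in_panel = taxon_map.organisms_in({TaxonGroup.VASCULAR_PLANT})
    vasc_here = tree_comp.organism_set({TaxonGroup.VASCULAR_PLANT})
    ancient = bool(vasc_in_panel) and (
        len(vasc_here) / max(len(vasc_in_panel), 1) >= cfg.ancient_plant_fraction
        and tree_comp.leaf_count({TaxonGroup.BRYOPHYTE, TaxonGroup.ALGA}) > 0
    )

    candidates = find_mixed_clades(gt, taxon_map, cfg)
    if not candidates:
        return HGTCall(
            gene_id=gene_id, category=Category.NO_HGT, ancient_in_plants=ancient
        )

    tentatives = [
        (cand, _tentative_category(cand, tree_comp, taxon_map, cfg))
        for cand in candidates
    ]
    named = [(c, t) for c, t in tentatives if t is not None]
    distinct = {t for _, t in named}

    cand = candidates[0]
    category: Category
    if not named or len(distinct) > 1:
        # mixed signal but no majority fit, or conflicting directions
        cand = named[0][0] if named else candidates[0]
        category = Category.UNCLEAR
    else:
        cand, category = named[0]

    flags: set[str] = set()
    bact_orgs = cand.composition.organism_set(BACTERIA)
    n_bact = len(bact_orgs)
    if category in DIRECTIONAL and n_bact < cfg.min_bacteria_genomes:
        category = Category.UNCLEAR
        flags.add(FLAG_SINGLE_BACTERIUM)

    key_support = normalize_support(cand.node.label)
    if key_support is None:
        flags.add(FLAG_NO_BOOTSTRAP)
    elif key_support < cfg.support_threshold:
        flags.add(FLAG_LOW_BOOTSTRAP)

    if cand.composition.leaf_count({TaxonGroup.AMORPHEA}) > 0 and category in (
        Category.BACTERIA_TO_PLANTS,
        Category.PLANTS_TO_BACTERIA,
    ):
        flags.add(FLAG_AMORPHEA)

    donor: Optional[str] = None
    acceptor: Optional[str] = None
    if category in DIRECTIONAL:
        sister_donor = _donor_from_sisters(cand.node, taxon_map, cfg.majority_fraction)
        if category in (Category.BACTERIA_TO_PLANTS, Category.BACTERIA_TO_EUKARYOTES):
            donor = sister_donor or "BACTERIA"
            acceptor = (
                "PLANTS" if category is Category.BACTERIA_TO_PLANTS else "EUKARYOTES"
            )
        else:
            donor = sister_donor or (
                "PLANTS" if category is Category.PLANTS_TO_BACTERIA else "EUKARYOTES"
            )
            acceptor = "BACTERIA"

    pa = bact_orgs and {taxon_map.group_of(o) for o in bact_orgs}
    if not bact_orgs:
        pa_involvement = "NONE"
    elif pa == {TaxonGroup.PA_BACTERIA}:
        pa_involvement = "PA"
    elif pa == {TaxonGroup.NPA_BACTERIA}:
        pa_involvement = "NPA"
    else:
        pa_involvement = "MIXED"

    return HGTCall(
        gene_id=gene_id,
        category=category,
        mixed_clade=frozenset(l.taxon.label for l in cand.node.leaf_iter()),
        key_support=key_support,
        donor_group=donor,
        acceptor_group=acceptor,
        pa_involvement=pa_involvement,
        n_bacterial_genomes=n_bact,
        flags=flags,
        ancient_in_plants=ancient,
    )


def summarize_calls(calls: list[HGTCall]) -> pd.DataFrame:
    """Per-category and per-PA tallies plus the percentage acquired by plants.

    The percentage acquired by plants is
    100 * |BACTERIA_TO_PLANTS| / (|BACTERIA_TO_PLANTS| + |PLANTS_TO_BACTERIA|)
    rounded half-up to an integer, NA when no plant-bacteria transfer exists.
    """
    cat_counts = {c: 0 for c in Category}
    pa_counts = {"PA": 0, "NPA": 0, "MIXED": 0, "NONE": 0}
    flag_counts: dict[str, int] = {}
    for call in calls:
        cat_counts[call.category] += 1
        pa_counts[call.pa_involvement] += 1
        for f in call.flags:
            flag_counts[f] = flag_counts.get(f, 0) + 1
    rows = [("n_trees", len(calls))]
    rows += [(f"category:{c.value}", n) for c, n in cat_counts.items()]
    rows += [(f"pa_involvement:{k}", n) for k, n in pa_counts.items()]
    rows += [(f"flag:{k}", n) for k, n in sorted(flag_counts.items())]
    rows.append(("pct_acquired_by_plants", pct_acquired_by_plants(calls)))
    return pd.DataFrame(rows, columns=["metric", "value"])


def pct_acquired_by_plants(calls_or_counts) -> object:
    """Percentage of plant-bacteria transfers that went into plants.

    Accepts either a list of calls or a (n_bacteria_to_plants,
    n_plants_to_bacteria) pair.  Rounds half-up to an integer; NA when there
    are no transfers in either direction.
    """
    if isinstance(calls_or_counts, tuple):
        b2p, p2b = calls_or_counts
    else:
        b2p = sum(1 for c in calls_or_counts if c.category is Category.BACTERIA_TO_PLANTS)
        p2b = sum(1 for c in calls_or_counts if c.category is Category.PLANTS_TO_BACTERIA)
    if b2p + p2b == 0:
        return "NA"
    pct = Decimal(100 * b2p) / Decimal(b2p + p2b)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def calls_to_frame(calls: list[HGTCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "category": c.category.value,
                "donor": c.donor_group or "",
                "acceptor": c.acceptor_group or "",
                "key_support": "" if c.key_support is None else c.key_support,
                "n_bacterial_genomes": c.n_bacterial_genomes,
                "pa_involvement": c.pa_involvement,
                "flags": ";".join(sorted(c.flags)),
                "ancient_in_plants": c.ancient_in_plants,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "category",
            "donor",
            "acceptor",
            "key_support",
            "n_bacterial_genomes",
            "pa_involvement",
            "flags",
            "ancient_in_plants",
        ],
    )


def classify_directory(
    tree_dir: str | Path,
    taxon_map: TaxonMap,
    cfg: Optional[ClassifyConfig] = None,
) -> list[HGTCall]:
    """Classify every Newick file in a directory (file stem = gene id)."""
    calls = []
    for path in sorted(Path(tree_dir).glob("*.nwk")):
        gt = GeneTree.from_file(path)
        calls.append(classify_tree(gt, taxon_map, cfg, gene_id=path.stem))
    return calls
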