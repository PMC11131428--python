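"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates, at desk scale, a panel of genomes spanning archaea,
a large interleaved set of plant-associated (PA) and non-plant-associated
(NPA) bacteria, and the eukaryotic supergroups, arranged on a fixed
caricature backbone

    ((ARCHAEA, BACTERIA), ((AMORPHEA, CRYPTISTA), (SAR, (ALGA, (BRYOPHYTE,
    VASCULAR_PLANT)))))

with random ultrametric within-group topologies.  Gene trees are copies of
the species tree with lognormal branch-length noise, random leaf loss,
assigned support values, and - when a transfer is planted - a
prune-and-regraft (SPR) that nests the acceptor clade inside the donor
group.  A planted transfer also restricts the gene's taxon distribution to
the realistic carrier set (a gene bacteria donated to plants is absent from
the other eukaryote supergroups, a plant gene acquired by three bacteria is
absent from the rest of the bacterial panel); the preset constructors below
encode this.

Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .classify import Category
from .enrichment import AnnotationUniverse
from .recency import PresenceMatrix
from .screen import HIT_COLUMNS
from .taxa import (
    BACTERIA,
    EUKARYOTES,
    PLANTS,
    TaxonGroup,
    TaxonInfo,
    TaxonMap,
)
from .trees import GeneTree

_PREFIX = {
    TaxonGroup.PA_BACTERIA: "PA",
    TaxonGroup.NPA_BACTERIA: "NPA",
    TaxonGroup.ARCHAEA: "Arch",
    TaxonGroup.VASCULAR_PLANT: "Vasc",
    TaxonGroup.BRYOPHYTE: "Bryo",
    TaxonGroup.ALGA: "Alga",
    TaxonGroup.SAR: "Sar",
    TaxonGroup.AMORPHEA: "Amor",
    TaxonGroup.CRYPTISTA: "Cryp",
}
_PREFIX_TO_GROUP = {v: k for k, v in _PREFIX.items()}

#: Example panel: a desk-scale caricature of the study's organism panel,
#: dominated by the two bacterial sets with a plant clade and a scatter of
#: other eukaryote supergroups.
DEFAULT_COUNTS: dict[TaxonGroup, int] = {
    TaxonGroup.PA_BACTERIA: 40,
    TaxonGroup.NPA_BACTERIA: 40,
    TaxonGroup.ARCHAEA: 4,
    TaxonGroup.VASCULAR_PLANT: 10,
    TaxonGroup.BRYOPHYTE: 2,
    TaxonGroup.ALGA: 2,
    TaxonGroup.SAR: 4,
    TaxonGroup.AMORPHEA: 4,
    TaxonGroup.CRYPTISTA: 0,
}

# node ages of the fixed backbone (root = 1.0, leaves = 0.0)
_AGE_ROOT = 1.0
_AGE_PROK = 0.9
_AGE_EUK = 0.9
_AGE_AMOR_CRYP = 0.7
_AGE_DIAPH = 0.8
_AGE_GREEN = 0.7
_AGE_PLANTS = 0.45
_CROWN = {
    TaxonGroup.ARCHAEA: 0.5,
    TaxonGroup.AMORPHEA: 0.5,
    TaxonGroup.CRYPTISTA: 0.3,
    TaxonGroup.SAR: 0.5,
    TaxonGroup.ALGA: 0.4,
    TaxonGroup.BRYOPHYTE: 0.2,
    TaxonGroup.VASCULAR_PLANT: 0.3,
}


@dataclass
class HGTSpec:
    """One planted transfer.

    ``n_transferred`` is the number of acceptor organisms carrying the gene
    (for transfers into bacteria: the bacteria moved by the SPR; for
    transfers into plants/eukaryotes: None means the whole acceptor clade).
    ``graft_depth`` is the number of donor-side leaves below the attachment
    edge, i.e. the size of the acceptor's sister clade at the graft point.
    """

    direction: Category
    donor_group: Optional[TaxonGroup] = None
    n_transferred: Optional[int] = None
    graft_depth: int = 3


@dataclass
class SimConfig:
    counts: dict[TaxonGroup, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    branch_noise_sigma: float = 0.1
    loss_prob: float = 0.05
    support_true_range: tuple[int, int] = (90, 100)
    support_other_range: tuple[int, int] = (40, 75)
    hgt: Optional[HGTSpec] = None
    bacteria_crown_age: float = 0.7
    paralog_prob: float = 0.0
    seed: int = 0


@dataclass
class SimTruth:
    gene_id: str
    has_hgt: bool
    direction: Optional[str] = None
    donor_group: Optional[str] = None
    acceptor_organisms: list[str] = field(default_factory=list)
    grafted_leaves: list[str] = field(default_factory=list)
    deleted_organisms: list[str] = field(default_factory=list)


def group_of_organism(organism_id: str) -> TaxonGroup:
    prefix = organism_id.split("_", 1)[0]
    try:
        return _PREFIX_TO_GROUP[prefix]
    except KeyError:
        raise ValueError(f"organism id {organism_id!r} has no known group prefix") from None


def organism_names(cfg: SimConfig) -> dict[TaxonGroup, list[str]]:
    return {
        g: [f"{_PREFIX[g]}_{i:03d}" for i in range(n)]
        for g, n in cfg.counts.items()
        if n > 0
    }


def taxon_map_for(cfg: SimConfig) -> TaxonMap:
    entries = {}
    for group, names in organism_names(cfg).items():
        for name in names:
            entries[name] = TaxonInfo(group=group)
    return TaxonMap(entries)


def _random_ultrametric(labels: list[str], age: float, rng) -> dendropy.Node:
    """Random ultrametric subtree over `labels` with crown age `age`."""
    node = dendropy.Node()
    if len(labels) == 1:
        node.age = 0.0
        node.sim_label = labels[0]
        return node
    node.age = age
    perm = rng.permutation(len(labels))
    k = int(rng.integers(1, len(labels)))
    parts = ([labels[i] for i in perm[:k]], [labels[i] for i in perm[k:]])
    for part in parts:
        child_age = 0.0 if len(part) == 1 else age * float(rng.uniform(0.5, 0.85))
        node.add_child(_random_ultrametric(part, child_age, rng))
    return node


def _join(age: float, children: list[Optional[dendropy.Node]]) -> Optional[dendropy.Node]:
    """Backbone node of the given age over the non-empty children."""
    kids = [c for c in children if c is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    node = dendropy.Node()
    node.age = age
    for c in kids:
        node.add_child(c)
    return node


def make_species_tree(cfg: SimConfig) -> GeneTree:
    """Fixed-backbone, random-within-group, ultrametric species tree.

    PA and NPA bacteria are interleaved inside one bacterial clade (the
    labels are ecological, not phylogenetic).  Deterministic in the seed.
    """
    names = organism_names(cfg)
    total = sum(len(v) for v in names.values())
    if total < 4:
        raise ValueError(f"need at least 4 organisms, got {total}")
    if cfg.hgt is not None:
        _validate_hgt_satisfiable(cfg, names)
    rng = np.random.default_rng(cfg.seed)

    def grp(group: TaxonGroup) -> Optional[dendropy.Node]:
        labels = names.get(group)
        if not labels:
            return None
        return _random_ultrametric(list(labels), _CROWN[group], rng)

    pa = names.get(TaxonGroup.PA_BACTERIA, [])
    npa = names.get(TaxonGroup.NPA_BACTERIA, [])
    bact_labels = [x for pair in zip(pa, npa) for x in pair]
    longer = pa if len(pa) > len(npa) else npa
    bact_labels += longer[min(len(pa), len(npa)):]
    bacteria = (
        _random_ultrametric(bact_labels, cfg.bacteria_crown_age, rng)
        if bact_labels
        else None
    )

    root = _join(
        _AGE_ROOT,
        [
            _join(_AGE_PROK, [grp(TaxonGroup.ARCHAEA), bacteria]),
            _join(
                _AGE_EUK,
                [
                    _join(_AGE_AMOR_CRYP, [grp(TaxonGroup.AMORPHEA), grp(TaxonGroup.CRYPTISTA)]),
                    _join(
                        _AGE_DIAPH,
                        [
                            grp(TaxonGroup.SAR),
                            _join(
                                _AGE_GREEN,
                                [
                                    grp(TaxonGroup.ALGA),
                                    _join(
                                        _AGE_PLANTS,
                                        [grp(TaxonGroup.BRYOPHYTE), grp(TaxonGroup.VASCULAR_PLANT)],
                                    ),
                                ],
                            ),
                        ],
                    ),
                ],
            ),
        ],
    )
    if root is None or root.age == 0.0:
        raise ValueError("species tree collapsed to fewer than 2 clades")

    tree = dendropy.Tree(seed_node=root)
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = round(node.parent_node.age - node.age, 10)
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tree.taxon_namespace.require_taxon(label=leaf.sim_label)
    return GeneTree(tree=tree, rooted=True)


def _validate_hgt_satisfiable(cfg: SimConfig, names) -> None:
    spec = cfg.hgt
    n_bact = len(names.get(TaxonGroup.PA_BACTERIA, [])) + len(
        names.get(TaxonGroup.NPA_BACTERIA, [])
    )
    n_plants = sum(len(names.get(g, [])) for g in PLANTS)
    n_euks = sum(len(names.get(g, [])) for g in EUKARYOTES)
    if spec.direction is Category.BACTERIA_TO_PLANTS and (n_plants == 0 or n_bact == 0):
        raise ValueError("BACTERIA_TO_PLANTS transfer needs plants and bacteria in the panel")
    if spec.direction is Category.BACTERIA_TO_EUKARYOTES and (n_euks == 0 or n_bact == 0):
        raise ValueError("BACTERIA_TO_EUKARYOTES transfer needs eukaryotes and bacteria")
    if spec.direction in (Category.PLANTS_TO_BACTERIA, Category.EUKARYOTES_TO_BACTERIA):
        if n_bact == 0 or n_euks == 0:
            raise ValueError("transfer into bacteria needs bacteria and eukaryotes")


def _node_ages(tree: dendropy.Tree) -> dict[int, float]:
    ages: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[id(node)] = 0.0
        else:
            child = node.child_nodes()[0]
            ages[id(node)] = ages[id(child)] + (child.edge.length or 0.0)
    return ages


def _leaves_below(node: dendropy.Node) -> list[str]:
    return [l.taxon.label for l in node.leaf_iter()]


def _pick_acceptor(tree, ages, spec: HGTSpec, rng):
    """The clade that will carry the transferred gene."""
    if spec.direction in (Category.BACTERIA_TO_PLANTS, Category.BACTERIA_TO_EUKARYOTES):
        groups = (
            PLANTS
            if spec.direction is Category.BACTERIA_TO_PLANTS
            else EUKARYOTES - {TaxonGroup.AMORPHEA, TaxonGroup.CRYPTISTA}
        )
        wanted = {
            l for l in _leaves_below(tree.seed_node) if group_of_organism(l) in groups
        }
        if spec.n_transferred is not None and spec.n_transferred < len(wanted):
            # a clade of exactly that many acceptor organisms
            node = _find_clade(tree, lambda labs: len(labs) == spec.n_transferred
                               and all(group_of_organism(l) in groups for l in labs), rng)
            if node is None:
                raise ValueError("graft impossible: no acceptor clade of requested size")
            return node
        node = tree.mrca(taxon_labels=sorted(wanted))
        if set(_leaves_below(node)) != wanted:
            raise ValueError("graft impossible: acceptor organisms are not a clade")
        return node
    # transfer into bacteria: a pure-bacterial clade of n_transferred leaves
    n = spec.n_transferred if spec.n_transferred is not None else 3
    node = _find_clade(
        tree,
        lambda labs: len(labs) == n
        and all(group_of_organism(l) in BACTERIA for l in labs),
        rng,
    )
    if node is None:
        raise ValueError(
            f"graft impossible: no pure bacterial clade of {n} genomes in the species tree"
        )
    return node


def _find_clade(tree, predicate, rng):
    candidates = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        labs = _leaves_below(node)
        if predicate(labs):
            candidates.append((tuple(sorted(labs)), node))
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[0])
    return candidates[int(rng.integers(0, len(candidates)))][1]


def _attachment_edges(tree, ages, spec: HGTSpec, exclude: set[int]):
    """Candidate attachment edges inside the donor region.

    An edge qualifies when all leaves below it belong to the donor side
    (bacteria for transfers into plants/eukaryotes, the donor eukaryote
    group(s) for transfers into bacteria) and their number equals
    graft_depth (fallback: nearest available count).
    """
    if spec.direction in (Category.BACTERIA_TO_PLANTS, Category.BACTERIA_TO_EUKARYOTES):
        allowed = BACTERIA
    elif spec.donor_group is not None:
        allowed = {spec.donor_group}
    elif spec.direction is Category.PLANTS_TO_BACTERIA:
        allowed = {TaxonGroup.VASCULAR_PLANT}
    else:
        allowed = EUKARYOTES
    pref_group = spec.donor_group
    pure = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or id(node) in exclude:
            continue
        labs = _leaves_below(node)
        groups = {group_of_organism(l) for l in labs}
        if groups <= allowed:
            pure.append((node, labs, groups))
    if not pure:
        raise ValueError("graft impossible: donor clade too small")
    exact = [t for t in pure if len(t[1]) == spec.graft_depth]
    if exact and pref_group is not None:
        best = [t for t in exact if t[2] == {pref_group}]
        exact = best or exact
    if not exact:
        target = min(pure, key=lambda t: abs(len(t[1]) - spec.graft_depth))
        exact = [t for t in pure if len(t[1]) == len(target[1])]
    return [t[0] for t in sorted(exact, key=lambda t: tuple(sorted(t[1])))]


def _apply_hgt(tree, ages, cfg: SimConfig, rng, truth: SimTruth) -> None:
    spec = cfg.hgt
    acceptor = _pick_acceptor(tree, ages, spec, rng)
    acceptor_age = ages[id(acceptor)]
    acceptor_leaves = _leaves_below(acceptor)
    exclude = {id(n) for n in acceptor.preorder_iter()}

    parent = acceptor.parent_node
    parent.remove_child(acceptor)

    targets = _attachment_edges(tree, ages, spec, exclude)
    target = targets[int(rng.integers(0, len(targets)))]
    t_parent = target.parent_node
    lo, hi = ages[id(target)], ages[id(t_parent)]
    lower = max(lo, acceptor_age + 0.01)
    if lower < hi:
        attach_h = (lower + hi) / 2.0
        stem = attach_h - acceptor_age
    else:
        attach_h = (lo + hi) / 2.0
        stem = 0.02
    graft = dendropy.Node()
    t_parent.add_child(graft)
    t_parent.remove_child(target)
    graft.add_child(target)
    graft.add_child(acceptor)
    graft.edge.length = hi - attach_h
    target.edge.length = attach_h - lo
    acceptor.edge.length = stem
    ages[id(graft)] = attach_h
    tree.suppress_unifurcations()

    truth.has_hgt = True
    truth.direction = spec.direction.value
    truth.donor_group = spec.donor_group.value if spec.donor_group else None
    truth.acceptor_organisms = sorted(acceptor_leaves)
    truth.grafted_leaves = sorted(acceptor_leaves)


def simulate_gene_tree(
    species_tree: GeneTree, cfg: SimConfig, gene_id: Optional[str] = None
) -> tuple[GeneTree, SimTruth]:
    """One gene tree: optional planted SPR, loss, branch noise, supports.

    The returned tree is unrooted (basal trifurcation), its leaves labelled
    ``organism|gene``.  Supports are drawn from ``support_true_range`` for
    branches present in the species tree and for the graft region - which
    with an SPR on a topology copy is every branch; ``support_other_range``
    would apply to branches matching no species-tree split.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_id = gene_id or f"g{cfg.seed}"
    gt = species_tree.copy()
    tree = gt.tree
    ages = _node_ages(tree)
    truth = SimTruth(gene_id=gene_id, has_hgt=False)

    if cfg.hgt is not None:
        _apply_hgt(tree, ages, cfg, rng, truth)

    # random loss, never dropping below 4 leaves
    if cfg.loss_prob > 0:
        leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
        n_left = len(leaves)
        doomed = []
        for leaf in leaves:
            if n_left <= 4:
                break
            if rng.random() < cfg.loss_prob:
                doomed.append(leaf)
                n_left -= 1
        for leaf in doomed:
            truth.deleted_organisms.append(leaf.taxon.label)
            node = leaf
            # removing the last leaf of a subtree empties its ancestors too
            while node.parent_node is not None and not node.child_nodes():
                parent = node.parent_node
                parent.remove_child(node)
                node = parent
        if doomed:
            tree.suppress_unifurcations()

    # lognormal branch-length noise
    if cfg.branch_noise_sigma > 0:
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is not None:
                node.edge.length *= float(rng.lognormal(0.0, cfg.branch_noise_sigma))

    # optional paralogs: duplicate a leaf into a shallow cherry
    if cfg.paralog_prob > 0:
        for leaf in list(tree.leaf_node_iter()):
            if rng.random() < cfg.paralog_prob:
                org = leaf.taxon.label
                stem_len = min(leaf.edge.length or 0.02, 0.02)
                leaf.taxon = None
                for copy_i in (1, 2):
                    child = dendropy.Node()
                    child.taxon = tree.taxon_namespace.require_taxon(
                        label=f"{org}\t{copy_i}"  # placeholder, renamed below
                    )
                    child.edge.length = stem_len
                    leaf.add_child(child)

    # supports on the 0-100 scale
    lo, hi = cfg.support_true_range
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        node.label = str(int(rng.integers(lo, hi + 1)))

    # organism -> organism|gene leaf labels
    for leaf in tree.leaf_node_iter():
        base = leaf.taxon.label
        if "\t" in base:
            org, copy_i = base.split("\t")
            leaf.taxon.label = f"{org}|{gene_id}.{copy_i}"
        else:
            leaf.taxon.label = f"{base}|{gene_id}"

    tree.deroot()
    gt.rooted = False
    return gt, truth


# ---------------------------------------------------------------------------
# presets: the study conditions for round-trip experiments

def clean_config(direction: Optional[Category], seed: int, **overrides) -> SimConfig:
    """Per-direction study conditions for planted-transfer experiments.

    "Clean" means no leaf loss, mild branch noise (sigma 0.05) and supports
    in [95, 100].  The taxon counts reflect the gene's realistic carrier set
    per direction (see module docstring).
    """
    base = dict(
        branch_noise_sigma=0.05,
        loss_prob=0.0,
        support_true_range=(95, 100),
        seed=seed,
    )
    if direction is None:
        return SimConfig(counts=dict(DEFAULT_COUNTS), seed=seed,
                         **{k: v for k, v in overrides.items()})
    if direction is Category.BACTERIA_TO_PLANTS:
        counts = {
            TaxonGroup.PA_BACTERIA: 30,
            TaxonGroup.NPA_BACTERIA: 30,
            TaxonGroup.ARCHAEA: 4,
            TaxonGroup.VASCULAR_PLANT: 10,
            TaxonGroup.BRYOPHYTE: 2,
        }
        hgt = HGTSpec(direction=direction, graft_depth=overrides.pop("graft_depth", 3))
        return SimConfig(counts=counts, hgt=hgt, **base, **overrides)
    if direction is Category.PLANTS_TO_BACTERIA:
        n = overrides.pop("n_transferred", 3)
        counts = {
            TaxonGroup.PA_BACTERIA: n,
            TaxonGroup.VASCULAR_PLANT: 10,
            TaxonGroup.BRYOPHYTE: 2,
            TaxonGroup.ALGA: 2,
            TaxonGroup.SAR: 4,
            TaxonGroup.AMORPHEA: 4,
        }
        hgt = HGTSpec(direction=direction, n_transferred=n,
                      graft_depth=overrides.pop("graft_depth", 3))
        return SimConfig(counts=counts, hgt=hgt, bacteria_crown_age=0.08,
                         **base, **overrides)
    if direction is Category.BACTERIA_TO_EUKARYOTES:
        counts = {
            TaxonGroup.PA_BACTERIA: 30,
            TaxonGroup.NPA_BACTERIA: 30,
            TaxonGroup.ARCHAEA: 4,
            TaxonGroup.VASCULAR_PLANT: 10,
            TaxonGroup.BRYOPHYTE: 2,
            TaxonGroup.ALGA: 2,
            TaxonGroup.SAR: 4,
        }
        hgt = HGTSpec(direction=direction, graft_depth=overrides.pop("graft_depth", 3))
        return SimConfig(counts=counts, hgt=hgt, **base, **overrides)
    if direction is Category.EUKARYOTES_TO_BACTERIA:
        n = overrides.pop("n_transferred", 3)
        counts = {
            TaxonGroup.PA_BACTERIA: n,
            TaxonGroup.VASCULAR_PLANT: 10,
            TaxonGroup.BRYOPHYTE: 2,
            TaxonGroup.ALGA: 2,
            TaxonGroup.SAR: 4,
            TaxonGroup.AMORPHEA: 4,
        }
        hgt = HGTSpec(direction=direction, donor_group=TaxonGroup.ALGA,
                      n_transferred=n, graft_depth=overrides.pop("graft_depth", 2))
        return SimConfig(counts=counts, hgt=hgt, bacteria_crown_age=0.08,
                         **base, **overrides)
    raise ValueError(f"no preset for direction {direction}")


# ---------------------------------------------------------------------------
# hit tables

def simulate_hits(
    n_pass: int, n_fail_identity: int, n_fail_coverage: int, seed: int = 0
) -> pd.DataFrame:
    """Extended outfmt-6 table with exactly n_pass records passing the screen.

    Passing records have pident in [40, 75] and both coverages in
    [0.86, 0.99]; identity failures have pident in [20, 34.9]; coverage
    failures have one coverage in [0.5, 0.79].  The boundary bands
    (pident in [34.95, 35) and coverage in (0.799, 0.801)) are never emitted,
    so the generated classes are unambiguous.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def coords(length: int, cov: float, low: bool) -> tuple[int, int]:
        span = int(np.floor(cov * length)) if low else int(np.ceil(cov * length))
        span = max(1, min(span, length))
        start = int(rng.integers(1, length - span + 2))
        return start, start + span - 1

    def add_row(pident: float, qcov: float, scov: float, i: int) -> None:
        qlen = int(rng.integers(150, 900))
        slen = int(rng.integers(150, 900))
        qlow, slow = qcov <= 0.80, scov <= 0.80
        qstart, qend = coords(qlen, qcov, qlow)
        sstart, send = coords(slen, scov, slow)
        aln = qend - qstart + 1
        rows.append(
            (
                f"PG{i % max(3, (n_pass + n_fail_identity + n_fail_coverage) // 3):05d}",
                f"BACT{i:05d}_p1",
                round(pident, 2),
                aln,
                int(aln * (1 - pident / 100)),
                int(rng.integers(0, 4)),
                qstart, qend, sstart, send,
                float(10.0 ** -rng.integers(20, 120)),
                round(float(rng.uniform(80, 900)), 1),
                qlen, slen,
            )
        )

    i = 0
    for _ in range(n_pass):
        add_row(float(rng.uniform(40, 75)), float(rng.uniform(0.86, 0.99)),
                float(rng.uniform(0.86, 0.99)), i)
        i += 1
    for _ in range(n_fail_identity):
        add_row(float(rng.uniform(20, 34.9)), float(rng.uniform(0.86, 0.99)),
                float(rng.uniform(0.86, 0.99)), i)
        i += 1
    for _ in range(n_fail_coverage):
        if rng.random() < 0.5:
            add_row(float(rng.uniform(40, 75)), float(rng.uniform(0.5, 0.79)),
                    float(rng.uniform(0.86, 0.99)), i)
        else:
            add_row(float(rng.uniform(40, 75)), float(rng.uniform(0.86, 0.99)),
                    float(rng.uniform(0.5, 0.79)), i)
        i += 1
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sample(frac=1.0, random_state=int(seed) % (2**32)).reset_index(drop=True)


def simulate_organelle_annotations(
    gene_ids: list[str], organelle_gene_ids: list[str], seed: int = 0
) -> pd.DataFrame:
    """Annotation rows marking some genes "located in" an organelle."""
    rng = np.random.default_rng(seed)
    organelles = ["mitochondrion", "chloroplast", "etioplast", "amyloplast",
                  "proplastid", "chromoplast"]
    rows = []
    organelle = set(organelle_gene_ids)
    for g in gene_ids:
        if g in organelle:
            rows.append((g, "located in", organelles[int(rng.integers(0, len(organelles)))]))
        else:
            rows.append((g, "involved in", "metabolic process"))
    return pd.DataFrame(rows, columns=["gene_id", "relationship_type", "term"])


# ---------------------------------------------------------------------------
# annotation universes with a planted enriched term

def simulate_annotations(
    N: int,
    terms: list[tuple[str, int]],
    planted: Optional[tuple[str, int, int]] = None,
    seed: int = 0,
    study_size: int = 0,
) -> tuple[AnnotationUniverse, set[str]]:
    """Background of N genes, each term over K random genes, and a study set.

    ``planted=(term, k, n)`` makes the study set of n genes contain exactly k
    genes of that term; without a planted term the study set is uniform
    random of ``study_size`` genes.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(N)])
    term_sizes = dict(terms)
    term_to_genes: dict[str, set[str]] = {}
    for term in sorted(term_sizes):
        K = term_sizes[term]
        if K > N:
            raise ValueError(f"term {term} size {K} exceeds background {N}")
        picks = rng.choice(N, size=K, replace=False)
        term_to_genes[term] = set(genes[picks])
    universe = AnnotationUniverse(background_genes=set(genes), term_to_genes=term_to_genes)

    if planted is None:
        study = set(genes[rng.choice(N, size=study_size, replace=False)]) if study_size else set()
        return universe, study

    term, k, n = planted
    if term not in term_to_genes:
        raise ValueError(f"planted term {term!r} not among the terms")
    inside = sorted(term_to_genes[term])
    outside = sorted(set(genes) - term_to_genes[term])
    if k > len(inside) or n - k > len(outside) or k > n:
        raise ValueError("unsatisfiable planted overlap")
    study = set(np.array(inside)[rng.choice(len(inside), size=k, replace=False)])
    study |= set(np.array(outside)[rng.choice(len(outside), size=n - k, replace=False)])
    return universe, study


# ---------------------------------------------------------------------------
# presence/absence matrices

def simulate_presence_matrix(
    gene_specs: list[tuple[str, str, int]],
    n_genera: int = 6,
    genomes_per_genus: int = 25,
    seed: int = 0,
) -> PresenceMatrix:
    """Genomes grouped into genera/families/phyla with planted gene patterns.

    ``gene_specs`` entries are (gene, rank, n_positive): the gene is present
    in n_positive genomes confined to the first taxon of the given rank
    ("genus", "family", "phylum") or spread across phyla for rank "all".
    """
    rng = np.random.default_rng(seed)
    genomes, entries = [], {}
    for g in range(n_genera):
        for i in range(genomes_per_genus):
            name = f"Gen{g}_sp{i:02d}"
            genomes.append(name)
            entries[name] = TaxonInfo(
                group=TaxonGroup.NPA_BACTERIA,
                genus=f"Genus{g}",
                family=f"Family{g // 2}",
                phylum=f"Phylum{g // 4}",
            )
    taxonomy = TaxonMap(entries)
    data = {}
    members_of = {
        "genus": [g for g in genomes if entries[g].genus == "Genus0"],
        "family": [g for g in genomes if entries[g].family == "Family0"],
        "phylum": [g for g in genomes if entries[g].phylum == "Phylum0"],
        "all": list(genomes),
    }
    for gene, rank, n_pos in gene_specs:
        pool = members_of[rank]
        if n_pos > len(pool):
            raise ValueError(f"{gene}: {n_pos} positives exceed {rank} size {len(pool)}")
        picks = rng.choice(len(pool), size=n_pos, replace=False)
        chosen = {pool[i] for i in picks}
        if rank == "all" and n_pos >= 2:
            # force spread over at least two phyla
            chosen.add(members_of["phylum"][0])
            other = [g for g in genomes if entries[g].phylum != "Phylum0"]
            chosen.add(other[0])
        data[gene] = [g in chosen for g in genomes]
    present = pd.DataFrame(data, index=pd.Index(genomes, name="genome_id"))
    return PresenceMatrix(present=present, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# full dataset on disk

def write_dataset(
    out_dir: str | Path,
    seed: int = 0,
    n_no_hgt: int = 10,
    n_b2p: int = 5,
    n_p2b: int = 5,
) -> dict:
    """Write every pipeline input into a directory, with a truth manifest."""
    from .taxa import write_taxon_map

    out = Path(out_dir)
    (out / "trees").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    panel_cfg = SimConfig(counts=dict(DEFAULT_COUNTS), seed=seed)
    tmap = taxon_map_for(panel_cfg)
    # pool the per-direction panels into one taxonomy
    for direction in (Category.BACTERIA_TO_PLANTS, Category.PLANTS_TO_BACTERIA):
        for org, info in taxon_map_for(clean_config(direction, seed)).entries.items():
            tmap.entries.setdefault(org, info)
    write_taxon_map(tmap, out / "taxonomy.tsv")

    truths = []
    jobs = [(None, n_no_hgt), (Category.BACTERIA_TO_PLANTS, n_b2p),
            (Category.PLANTS_TO_BACTERIA, n_p2b)]
    idx = 0
    for direction, count in jobs:
        for _ in range(count):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cfg = clean_config(direction, sub_seed)
            if direction is None:
                cfg.branch_noise_sigma, cfg.loss_prob = 0.1, 0.05
            species = make_species_tree(cfg)
            gene_id = f"gene{idx:04d}"
            gt, truth = simulate_gene_tree(species, cfg, gene_id=gene_id)
            gt.write(out / "trees" / f"{gene_id}.nwk")
            truths.append(asdict(truth))
            idx += 1

    hits = simulate_hits(12, 20, 8, seed=seed)
    hits.to_csv(out / "hits.tsv", sep="\t", index=False, header=False)
    gene_ids = sorted(set(hits["qseqid"]))
    ann = simulate_organelle_annotations(gene_ids, gene_ids[:1], seed=seed)
    ann.to_csv(out / "organelle_annotations.tsv", sep="\t", index=False)

    universe, study = simulate_annotations(
        N=2000, terms=[("GO:0016998", 30), ("GO:0030245", 25), ("GO:0009058", 60)],
        planted=("GO:0016998", 6, 16), seed=seed
    )
    rows = [(g, t) for t, gs in universe.term_to_genes.items() for g in sorted(gs)]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        out / "go_annotations.tsv", sep="\t", index=False
    )
    (out / "study_set.txt").write_text("\n".join(sorted(study)) + "\n")
    pd.Series(sorted(universe.background_genes)).to_csv(
        out / "background.txt", index=False, header=False
    )

    pm = simulate_presence_matrix(
        [("CHI_like", "genus", 22), ("core_gene", "all", 150)],
        seed=seed,
    )
    pm.present.astype(int).to_csv(out / "presence.tsv", sep="\t")
    write_taxon_map(pm.taxonomy, out / "presence_taxonomy.tsv")

    manifest = {
        "seed": seed,
        "n_trees": idx,
        "truths": truths,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
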