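"""Gene-tree container and Newick I/O.

Trees are dendropy trees wrapped with a ``rooted`` flag.  Leaf labels are
``organism|gene`` strings; internal-node labels are read as branch support
values and may be on either the 0-1 or the 0-100 scale (normalization happens
in :mod:`phylohgt.classify`).  Underscores in labels are preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy


@dataclass
class GeneTree:
    tree: dendropy.Tree
    rooted: bool

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        rooted = len(tree.seed_node.child_nodes()) == 2
        tree.is_rooted = rooted
        return cls(tree=tree, rooted=rooted)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneTree":
        return cls.from_newick(Path(path).read_text(encoding="utf-8"))

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            + "\n"
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick(), encoding="utf-8")

    def leaf_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def copy(self) -> "GeneTree":
        return GeneTree.from_newick(self.to_newick())


def leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")
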