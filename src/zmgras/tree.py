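"""Minimal phylogenetic tree container shared by the phylogeny and IO layers.

The tree is stored as plain parent/child nodes with branch lengths and
optional integer bootstrap supports on internal nodes.  Conversion to and
from :class:`skbio.TreeNode` is provided so that midpoint rooting and
Newick parsing go through scikit-bio rather than bespoke code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import skbio

from .errors import ValidationError

_FORBIDDEN = re.compile(r"[(),:;\s\[\]']")


def sanitize_label(label: str) -> str:
    """Replace characters with structural meaning in Newick by underscores."""
    return _FORBIDDEN.sub("_", label)


@dataclass
class Clade:
    """One node of a phylogenetic tree.

    ``name`` is set for leaves (the gene/protein id); ``support`` is an
    integer bootstrap percentage attached to internal nodes.
    """

    name: Optional[str] = None
    branch_length: Optional[float] = None
    support: Optional[int] = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Clade"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """A (typically unrooted) tree over N labelled leaves.

    The root is a bookkeeping node; NJ returns a trifurcating root, in
    which case the tree should be interpreted as unrooted.
    """

    root: Clade

    def leaves(self) -> list[Clade]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions induced by internal edges.

        Each bipartition is canonicalised as the frozenset of the side that
        does *not* contain the lexicographically smallest leaf, making
        comparisons across differently rooted trees of the same leaf set
        well defined.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(leaf.name for leaf in node.walk() if leaf.is_leaf)
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                parts.add(side)
        return parts

    # -- scikit-bio interop -------------------------------------------------

    def to_skbio(self) -> skbio.TreeNode:
        def convert(node: Clade) -> skbio.TreeNode:
            if node.is_leaf:
                name = node.name
            else:
                name = None if node.support is None else str(node.support)
            out = skbio.TreeNode(name=name, length=node.branch_length)
            out.extend([convert(c) for c in node.children])
            return out

        return convert(self.root)

    @classmethod
    def from_skbio(cls, tree: skbio.TreeNode) -> "PhyloTree":
        def convert(node: skbio.TreeNode) -> Clade:
            clade = Clade(branch_length=node.length)
            if node.is_tip():
                clade.name = node.name
            elif node.name is not None:
                try:
                    clade.support = int(round(float(node.name)))
                except ValueError:
                    clade.name = node.name
            clade.children = [convert(c) for c in node.children]
            return clade

        return cls(root=convert(tree))

    def midpoint_rooted(self) -> "PhyloTree":
        """Return a copy rooted at the midpoint of the longest leaf-to-leaf path."""
        rooted = self.to_skbio().root_at_midpoint()
        return PhyloTree.from_skbio(rooted)


def _newick_node(node: Clade) -> str:
    if node.is_leaf:
        if node.name is None:
            raise ValidationError("leaf without a name cannot be serialised")
        text = sanitize_label(node.name)
    else:
        inner = ",".join(_newick_node(c) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        text = f"({inner}){label}"
    if node.branch_length is not None:
        text += f":{node.branch_length:.6f}"
    return text


def write_newick(tree: PhyloTree, path) -> None:
    """Serialise a tree to Newick.

    Branch lengths are written with 6 decimals and bootstrap supports as
    integer internal-node labels; forbidden characters in leaf names are
    replaced by underscores.
    """
    if len(tree.leaves()) < 2:
        raise ValidationError("a Newick tree needs at least 2 leaves")
    with open(path, "w") as fh:
        fh.write(_newick_node(tree.root) + ";\n")


def read_newick(path) -> PhyloTree:
    """Parse a Newick file (via scikit-bio) into a :class:`PhyloTree`."""
    return PhyloTree.from_skbio(
        skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)
    )
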