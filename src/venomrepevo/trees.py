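"""Phylogenetic tree containers and I/O.

Trees are held as lightweight :class:`TreeNode` objects (label, branch
length, bootstrap support, children).  Parsing and midpoint rooting are
delegated to dendropy; serialization is a direct recursive writer so the
placement of support values (IQ-Tree style internal-node labels) is under
our control.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "parse_newick",
    "to_newick",
    "read_trees_nexus",
    "write_trees_nexus",
    "collapse_low_support",
    "midpoint_root",
    "bipartitions",
    "leaf_labels",
]


@dataclass
class TreeNode:
    """A rooted (sub)tree node.

    label
        Taxon name for leaves; optional clade name for internal nodes.
    length
        Branch length of the edge above this node, or ``None``.
    support
        Bootstrap support (percent, 0-100) of the edge above this node;
        meaningful only on internal non-root nodes.
    """

    label: str = ""
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    # -- structure ---------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        return TreeNode(
            label=self.label,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )

    def find(self, label: str) -> Optional["TreeNode"]:
        """First node (preorder) whose label matches, else None."""
        for node in self.preorder():
            if node.label == label:
                return node
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({to_newick(self)})"


def leaf_labels(tree: TreeNode) -> list[str]:
    return [n.label for n in tree.leaves()]


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree, support_style: str) -> TreeNode:
    def convert(dnode, is_root: bool) -> TreeNode:
        node = TreeNode()
        if dnode.taxon is not None:
            node.label = dnode.taxon.label
        elif dnode.label:
            node.label = dnode.label
        node.length = dnode.edge.length
        children = dnode.child_nodes()
        if children:
            node.children = [convert(c, False) for c in children]
            if not is_root:
                node.support = _extract_support(dnode, support_style)
                if node.support is not None and node.label == (dnode.label or ""):
                    # label was consumed as a support value
                    node.label = ""
        return node

    return convert(dtree.seed_node, True)


def _extract_support(dnode, support_style: str) -> Optional[float]:
    if support_style == "label":
        text = dnode.label
    elif support_style == "comment":
        text = dnode.comments[0] if dnode.comments else None
    else:
        raise ValueError(f"unknown support_style: {support_style!r}")
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def parse_newick(text: str, support_style: str = "label") -> TreeNode:
    """Parse a single Newick string into a :class:`TreeNode`.

    ``support_style`` selects where bootstrap values live: ``"label"``
    (internal node labels, the IQ-Tree convention) or ``"comment"``
    (bracketed comments after the node).  Internal labels that do not
    parse as numbers are kept as clade names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy error messages carry the position
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree = _from_dendropy(dtree, support_style)
    seen: set[str] = set()
    for leaf in tree.leaves():
        if not leaf.label:
            raise ValueError("malformed Newick: leaf without a label")
        if leaf.label in seen:
            raise ValueError(f"duplicate leaf label: {leaf.label!r}")
        seen.add(leaf.label)
    return tree


def to_newick(tree: TreeNode, include_supports: bool = True,
              include_lengths: bool = True, terminate: bool = True) -> str:
    """Serialize to Newick with supports as internal-node labels."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            out = _quote(node.label)
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            tag = ""
            if not is_root and include_supports and node.support is not None:
                tag = _fmt_num(node.support)
            elif node.label:
                tag = _quote(node.label)
            out = f"({inner}){tag}"
        if include_lengths and node.length is not None:
            out += f":{_fmt_num(node.length)}"
        return out

    text = fmt(tree, True)
    return text + ";" if terminate else text


def _fmt_num(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


_UNSAFE = set(" (),:;[]'")


def _quote(label: str) -> str:
    if any(ch in _UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_trees_nexus(source: str | io.TextIOBase, support_style: str = "label") -> list[TreeNode]:
    """Read all trees from a NEXUS TREES block (path or file object)."""
    kwargs = dict(schema="nexus", suppress_internal_node_taxa=True,
                  preserve_underscores=True)
    if isinstance(source, str):
        trees = dendropy.TreeList.get(path=source, **kwargs)
    else:
        trees = dendropy.TreeList.get(file=source, **kwargs)
    return [_from_dendropy(t, support_style) for t in trees]


def write_trees_nexus(trees: list[TreeNode], dest: str | io.TextIOBase,
                      names: Optional[list[str]] = None) -> None:
    """Write trees as a minimal NEXUS TREES block (PAUP*-style interchange)."""
    names = names or [f"tree_{i + 1}" for i in range(len(trees))]
    lines = ["#NEXUS", "BEGIN TREES;"]
    for name, tree in zip(names, trees):
        lines.append(f"    TREE {name} = {to_newick(tree)}")
    lines.append("END;")
    text = "\n".join(lines) + "\n"
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            fh.write(text)
    else:
        dest.write(text)


# ---------------------------------------------------------------------------
# Manipulation
# ---------------------------------------------------------------------------

def collapse_low_support(tree: TreeNode, threshold: float = 50.0) -> TreeNode:
    """Collapse internal non-root edges with support below ``threshold``.

    Children of a collapsed node are spliced into its parent (polytomy).
    Nodes without a support value are kept.  Idempotent; returns a copy.
    """
    out = tree.copy()

    def visit(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        for child in node.children:
            visit(child)
            if (not child.is_leaf and child.support is not None
                    and child.support < threshold):
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    visit(out)
    return out


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Reroot at the midpoint of the longest leaf-to-leaf path.

    Requires branch lengths on every non-root edge.  Pairwise leaf path
    lengths are preserved.  Delegates to dendropy's midpoint rerooting.
    """
    for node in tree.postorder():
        if node is not tree and node.length is None:
            raise ValueError("midpoint rooting requires branch lengths on all edges")
    if len(tree.leaves()) < 2:
        raise ValueError("midpoint rooting requires at least two leaves")
    # round-trip through dendropy, carrying supports as labels
    dtree = dendropy.Tree.get(
        data=to_newick(tree), schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True)
    dtree.reroot_at_midpoint(update_bipartitions=False)
    return _from_dendropy(dtree, "label")


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each encoded as the half not
    containing the lexicographically smallest leaf label."""
    all_leaves = frozenset(leaf_labels(tree))
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def visit(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(visit(c) for c in node.children))
        side = below if anchor not in below else all_leaves - below
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
        return below

    visit(tree)
    return splits
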