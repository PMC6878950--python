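"""The canonical centipede species tree and order taxonomy.

Nine study species spanning the five extant centipede orders, with the
accepted order-level topology: Scutigeromorpha sister to all other
centipedes (Pleurostigmophora), Craterostigmomorpha sister to Epimorpha
(together Phylactometria), and Epimorpha comprising Geophilomorpha plus
Scolopendromorpha.  Internal nodes carry the standard clade names so that
ancestral-state output can refer to, e.g., the "Epimorpha" ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .trees import TreeNode, parse_newick, leaf_labels

__all__ = [
    "SpeciesTree",
    "canonical_species_tree",
    "FULL_NAMES",
    "ORDERS",
    "CANONICAL_NEWICK",
    "CANONICAL_NEWICK_WITH_SV",
]

FULL_NAMES = {
    "Sc": "Scutigera coleoptrata",
    "Tl": "Thereuopoda longicornis",
    "Lf": "Lithobius forficatus",
    "Ct": "Craterostigmus tasmanianus",
    "Stm": "Strigamia maritima",
    "Er": "Ethmostigmus rubripes",
    "Cw": "Cormocephalus westwoodi",
    "Ss": "Scolopendra subspinipes",
    "Sm": "Scolopendra morsitans",
    "Sv": "Scolopendra viridis",
}

ORDERS = {
    "Sc": "Scutigeromorpha",
    "Tl": "Scutigeromorpha",
    "Lf": "Lithobiomorpha",
    "Ct": "Craterostigmomorpha",
    "Stm": "Geophilomorpha",
    "Er": "Scolopendromorpha",
    "Cw": "Scolopendromorpha",
    "Ss": "Scolopendromorpha",
    "Sm": "Scolopendromorpha",
    "Sv": "Scolopendromorpha",
}

CANONICAL_NEWICK = (
    "((Sc,Tl)Scutigeromorpha,"
    "(Lf,(Ct,(Stm,(Er,(Cw,(Ss,Sm)Scolopendra)Scolopendrinae)"
    "Scolopendromorpha)Epimorpha)Phylactometria)Pleurostigmophora)Chilopoda;"
)

# Scolopendra viridis is the closest relative of Cormocephalus westwoodi
CANONICAL_NEWICK_WITH_SV = (
    "((Sc,Tl)Scutigeromorpha,"
    "(Lf,(Ct,(Stm,(Er,((Cw,Sv)Cormocephalus_Sv,(Ss,Sm)Scolopendra)Scolopendrinae)"
    "Scolopendromorpha)Epimorpha)Phylactometria)Pleurostigmophora)Chilopoda;"
)


@dataclass
class SpeciesTree:
    """A rooted species tree plus an order-level taxonomy of its leaves."""

    root: TreeNode
    taxonomy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [t for t in self.leaf_set if t not in self.taxonomy]
        if missing:
            raise ValueError(f"taxa without a taxonomy entry: {missing}")
        self._assign_node_ids()

    def _assign_node_ids(self) -> None:
        """Give every node a stable, unique id: leaf label, internal clade
        label where present, else node<postorder index>."""
        self.node_ids: dict[int, str] = {}
        used: set[str] = set()
        for i, node in enumerate(self.root.postorder()):
            name = node.label or f"node{i}"
            if name in used:
                name = f"{name}_{i}"
            used.add(name)
            self.node_ids[id(node)] = name

    @property
    def leaf_set(self) -> set[str]:
        return set(leaf_labels(self.root))

    def node_id(self, node: TreeNode) -> str:
        return self.node_ids[id(node)]

    def node_by_id(self, node_id: str) -> TreeNode:
        for node in self.root.postorder():
            if self.node_id(node) == node_id:
                return node
        raise KeyError(node_id)

    def parent_map(self) -> dict[int, Optional[TreeNode]]:
        parents: dict[int, Optional[TreeNode]] = {id(self.root): None}
        for node in self.root.preorder():
            for child in node.children:
                parents[id(child)] = node
        return parents

    def lca(self, taxa: set[str]) -> TreeNode:
        """Least common ancestor of a set of leaf labels."""
        if not taxa:
            raise ValueError("lca of an empty taxon set")
        unknown = taxa - self.leaf_set
        if unknown:
            raise KeyError(f"taxa not in species tree: {sorted(unknown)}")

        def visit(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                return node if node.label in taxa else None
            hits = [r for r in (visit(c) for c in node.children) if r is not None]
            covered = {l.label for h in hits for l in h.leaves()} if hits else set()
            if len(hits) > 1 or (hits and taxa <= covered):
                return node if len(hits) > 1 else hits[0]
            return hits[0] if hits else None

        node = visit(self.root)
        assert node is not None
        # walk down while a single child covers all taxa
        while not node.is_leaf:
            covering = [c for c in node.children
                        if taxa <= {l.label for l in c.leaves()}]
            if covering:
                node = covering[0]
            else:
                break
        return node

    def orders_of(self, taxa: set[str]) -> set[str]:
        return {self.taxonomy[t] for t in taxa}


def canonical_species_tree(include_viridis: bool = False) -> SpeciesTree:
    """The study's nine-species tree (ten with Scolopendra viridis)."""
    newick = CANONICAL_NEWICK_WITH_SV if include_viridis else CANONICAL_NEWICK
    root = parse_newick(newick)
    taxa = set(leaf_labels(root))
    taxonomy = {t: ORDERS[t] for t in taxa}
    return SpeciesTree(root=root, taxonomy=taxonomy)
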