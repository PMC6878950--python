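"""Gene-tree / species-tree reconciliation and recruitment multiplicity.

Gene trees for toxin families carry one leaf per sequence, labeled
``<species>_<sequence id>``; leaves confirmed in a venom proteome are
flagged.  LCA reconciliation maps every gene-tree node to the least
common ancestor of its descendants' species; a node mapping to the same
species-tree node as one of its children marks a gene duplication placed
on that species-tree node.  The proteome flag, optimized on the gene
tree as a binary character, yields the minimal number of independent
recruitments of the family into venom, which is emitted as an override
for the species-level character optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .trees import TreeNode
from .species import SpeciesTree
from .parsimony import DELTRAN, OverrideRecord, optimize_character, _resolve

__all__ = [
    "AnnotatedGeneTree",
    "ReconciliationResult",
    "annotate_proteome",
    "lca_reconcile",
    "recruitment_multiplicity",
    "split_leaf_label",
]


def split_leaf_label(label: str) -> tuple[str, str]:
    """``Sm_toxin7`` -> (``Sm``, ``toxin7``); no underscore -> id empty."""
    species, _, seq_id = label.partition("_")
    return species, seq_id


@dataclass
class AnnotatedGeneTree:
    """A rooted gene tree with proteome-confirmation and outgroup flags."""

    tree: TreeNode
    proteome_flags: dict[str, bool] = field(default_factory=dict)
    outgroup_flags: dict[str, bool] = field(default_factory=dict)
    family: str = ""

    def leaf_species(self, leaf_label: str) -> str:
        return split_leaf_label(leaf_label)[0]

    def validate_against(self, species_tree: SpeciesTree) -> None:
        for leaf in self.tree.leaves():
            if self.outgroup_flags.get(leaf.label):
                continue
            sp = self.leaf_species(leaf.label)
            if sp not in species_tree.leaf_set:
                raise KeyError(
                    f"gene-tree leaf {leaf.label!r} resolves to species "
                    f"{sp!r}, absent from the species tree and not an outgroup")


@dataclass
class ReconciliationResult:
    """LCA mapping plus inferred duplications.

    ``species_map``: gene-node id -> species-tree node id.
    ``duplications``: list of (gene-node id, species-tree node id).
    A polytomy counts as at most one duplication even when several
    children share its mapping (the conservative minimum).
    """

    species_map: dict[str, str]
    duplications: list[tuple[str, str]]

    @property
    def duplication_count(self) -> int:
        return len(self.duplications)

    def duplications_by_species_node(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, sp_node in self.duplications:
            out[sp_node] = out.get(sp_node, 0) + 1
        return out


def annotate_proteome(gene_tree: TreeNode, hits: dict[str, set[str]],
                      family: str = "",
                      outgroup: Optional[Callable[[str], bool]] = None
                      ) -> AnnotatedGeneTree:
    """Flag gene-tree leaves confirmed in the venom proteome.

    ``hits`` maps species -> set of confirmed sequence ids.  ``outgroup``
    optionally classifies leaf labels as non-centipede outgroups.
    """
    leaves = gene_tree.leaves()
    labels = [l.label for l in leaves]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate gene-tree leaf ids: {dupes}")
    flags: dict[str, bool] = {}
    out_flags: dict[str, bool] = {}
    for label in labels:
        sp, seq = split_leaf_label(label)
        flags[label] = seq in hits.get(sp, set())
        out_flags[label] = bool(outgroup(label)) if outgroup else False
    return AnnotatedGeneTree(tree=gene_tree, proteome_flags=flags,
                             outgroup_flags=out_flags, family=family)


def _prune_outgroups(annotated: AnnotatedGeneTree) -> TreeNode:
    """Drop outgroup leaves (used for rooting only); keep the ingroup."""
    tree = annotated.tree.copy()

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            return None if annotated.outgroup_flags.get(node.label) else node
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = kept
        return node

    pruned = prune(tree)
    if pruned is None:
        raise ValueError("gene tree contains only outgroup leaves")
    return pruned


def lca_reconcile(gene_tree: AnnotatedGeneTree,
                  species_tree: SpeciesTree) -> ReconciliationResult:
    """Standard LCA reconciliation of a rooted gene tree."""
    gene_tree.validate_against(species_tree)
    ingroup = _prune_outgroups(gene_tree)
    _, gids = _resolve(ingroup)

    mapping: dict[int, TreeNode] = {}
    species_map: dict[str, str] = {}
    duplications: list[tuple[str, str]] = []

    def visit(node: TreeNode) -> set[str]:
        if node.is_leaf:
            sp = gene_tree.leaf_species(node.label)
            mapping[id(node)] = species_tree.lca({sp})
            species_map[gids[id(node)]] = species_tree.node_id(mapping[id(node)])
            return {sp}
        taxa: set[str] = set()
        for c in node.children:
            taxa |= visit(c)
        mapping[id(node)] = species_tree.lca(taxa)
        species_map[gids[id(node)]] = species_tree.node_id(mapping[id(node)])
        if any(mapping[id(c)] is mapping[id(node)] for c in node.children):
            duplications.append((gids[id(node)],
                                 species_tree.node_id(mapping[id(node)])))
        return taxa

    visit(ingroup)
    return ReconciliationResult(species_map=species_map,
                                duplications=duplications)


def recruitment_multiplicity(annotated: AnnotatedGeneTree,
                             species_tree: SpeciesTree
                             ) -> list[OverrideRecord]:
    """Minimal number of independent venom recruitments of a family.

    The proteome flag is optimized on the gene tree under the
    loss-minimizing (DELTRAN) rule, with the root pinned to unflagged
    when outgroup sequences are present (outgroups are never venom
    components).  The number of gains is the number of independent
    origins; loss events mark within-clade losses of venom expression.
    Returns one OverrideRecord (single_origin or multi_origin) for the
    family, ready for the species-level optimization.
    """
    annotated.validate_against(species_tree)
    tree = annotated.tree
    char = {l.label: (1 if annotated.proteome_flags.get(l.label) else 0)
            for l in tree.leaves()}
    root, ids = _resolve(tree)
    pins = None
    if any(annotated.outgroup_flags.get(l.label) for l in tree.leaves()):
        pins = {ids[id(root)]: 0}
    from .parsimony import _optimize
    recon = _optimize(root, ids, char, DELTRAN, pins=pins,
                      count_root_origin=True, family=annotated.family)
    origins = recon.gains
    expression_losses = recon.losses
    if origins <= 1:
        rec = OverrideRecord(family=annotated.family, kind="single_origin")
    else:
        rec = OverrideRecord(family=annotated.family, kind="multi_origin",
                             count=origins)
    rec.expression_losses = expression_losses  # advisory annotation
    return [rec]
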