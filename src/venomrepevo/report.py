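"""Whole-repertoire ancestral reconstruction and event summaries.

Runs one ACCTRAN or DELTRAN optimization per toxin family over a fixed
species tree, assembles ancestral venom cocktails (the set of families
present at each internal node), per-branch gain/loss event tables, and
the summary statistics of interest: total recruitments and losses,
single versus convergent recruitment, convergent losses, and the split
of events between order-internal branches and the shared stem lineages.

Branch classification convention: a branch is "within-order" iff every
descendant leaf of its child node belongs to one order (order stem
branches included); otherwise it is a shared stem-lineage branch.  The
root-origination recruitments of ancestrally present families sit on the
root (centipede stem) branch and count as stem events when the
root-origination convention is on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .matrix import RepertoireMatrix
from .species import SpeciesTree
from .parsimony import (CharacterReconstruction, OverrideRecord,
                        apply_overrides, optimize_character)
from .trees import TreeNode, to_newick

__all__ = ["EvolutionReport", "EventSummary", "reconstruct_venom_evolution",
           "summarize_events", "lineage_deltas", "convention_grid"]


@dataclass
class EvolutionReport:
    method: str
    reconstructions: dict[str, CharacterReconstruction]
    ancestral_cocktails: dict[str, set[str]]
    branch_events: dict[str, list[tuple[str, str]]]
    tree: SpeciesTree
    count_root_origin: bool = True

    def cocktail(self, node_id: str) -> set[str]:
        return set(self.ancestral_cocktails.get(node_id, set()))

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "count_root_origin": self.count_root_origin,
            "ancestral_cocktails": {k: sorted(v) for k, v in
                                    self.ancestral_cocktails.items()},
            "branch_events": {k: [list(e) for e in v]
                              for k, v in self.branch_events.items()},
            "per_family_length": {f: r.length
                                  for f, r in self.reconstructions.items()},
        }
        return json.dumps(payload, indent=1, ensure_ascii=False)

    def cocktail_table(self) -> pd.DataFrame:
        rows = [{"node": k, "n_families": len(v),
                 "families": ";".join(sorted(v))}
                for k, v in sorted(self.ancestral_cocktails.items())]
        return pd.DataFrame(rows)

    def event_table(self) -> pd.DataFrame:
        rows = [{"branch": b, "family": fam, "event": kind}
                for b, evs in sorted(self.branch_events.items())
                for fam, kind in evs]
        return pd.DataFrame(rows, columns=["branch", "family", "event"])

    def annotated_newick(self) -> str:
        """Species tree with cocktail sizes as node comments."""
        tree = self.tree.root.copy()
        # map copied nodes positionally (copy preserves traversal order)
        orig = list(self.tree.root.postorder())
        for node, onode in zip(tree.postorder(), orig):
            nid = self.tree.node_id(onode)
            size = len(self.ancestral_cocktails.get(nid, set()))
            suffix = f"[&cocktail={size}]"
            node.label = (node.label or nid) + suffix if not node.is_leaf \
                else node.label + suffix
        return to_newick(tree, include_supports=False, include_lengths=False)


@dataclass
class EventSummary:
    total_events: int
    total_gains: int
    total_losses: int
    families_single_recruitment: list[str]
    families_convergent_recruitment: list[str]
    families_convergent_loss: list[str]
    within_order_events: int
    stem_events: int
    per_species_event_totals: dict[str, int]

    @property
    def n_single(self) -> int:
        return len(self.families_single_recruitment)

    @property
    def n_convergent(self) -> int:
        return len(self.families_convergent_recruitment)

    def as_dict(self) -> dict:
        return {
            "total_events": self.total_events,
            "total_gains": self.total_gains,
            "total_losses": self.total_losses,
            "n_single_recruitment": self.n_single,
            "n_convergent_recruitment": self.n_convergent,
            "families_convergent_loss": sorted(self.families_convergent_loss),
            "within_order_events": self.within_order_events,
            "stem_events": self.stem_events,
            "per_species_event_totals": dict(self.per_species_event_totals),
        }


def reconstruct_venom_evolution(matrix: RepertoireMatrix, tree: SpeciesTree,
                                method: str,
                                overrides: Optional[list[OverrideRecord]] = None,
                                count_root_origin: bool = True
                                ) -> EvolutionReport:
    """One reconstruction per family; cocktails and branch events assembled."""
    extra = set(matrix.species) - tree.leaf_set
    if extra:
        raise ValueError(f"matrix species not in species tree: {sorted(extra)}")
    overrides = overrides or []
    recons: dict[str, CharacterReconstruction] = {}
    cocktails: dict[str, set[str]] = {tree.node_id(n): set()
                                      for n in tree.root.postorder()}
    branch_events: dict[str, list[tuple[str, str]]] = {}
    for fam in matrix.families:
        recon = optimize_character(tree, matrix.character(fam), method,
                                   count_root_origin=count_root_origin,
                                   family=fam)
        recon = apply_overrides(recon, overrides)
        recons[fam] = recon
        for node_id, state in recon.node_states.items():
            if state == 1:
                cocktails[node_id].add(fam)
        for branch, kind in recon.events:
            branch_events.setdefault(branch, []).append((fam, kind))
    return EvolutionReport(method=method, reconstructions=recons,
                           ancestral_cocktails=cocktails,
                           branch_events=branch_events, tree=tree,
                           count_root_origin=count_root_origin)


def _branch_is_within_order(tree: SpeciesTree, child_id: str,
                            taxonomy: dict[str, str]) -> bool:
    node = tree.node_by_id(child_id)
    orders = {taxonomy[l.label] for l in node.leaves()}
    return len(orders) == 1


def summarize_events(report: EvolutionReport,
                     taxonomy: dict[str, str]) -> EventSummary:
    tree = report.tree
    root_id = tree.node_id(tree.root)
    total_gains = total_losses = within = stem = 0
    per_family_gains: dict[str, int] = {}
    per_family_losses: dict[str, int] = {}
    for branch, events in report.branch_events.items():
        for fam, kind in events:
            if kind == "gain":
                total_gains += 1
                per_family_gains[fam] = per_family_gains.get(fam, 0) + 1
            else:
                total_losses += 1
                per_family_losses[fam] = per_family_losses.get(fam, 0) + 1
            if branch == root_id:
                stem += 1  # root origination: centipede stem
            elif _branch_is_within_order(tree, branch, taxonomy):
                within += 1
            else:
                stem += 1
    single = sorted(f for f, g in per_family_gains.items() if g == 1)
    convergent = sorted(f for f, g in per_family_gains.items() if g > 1)
    convergent_loss = sorted(f for f, l in per_family_losses.items() if l > 1)

    # per-species totals: events on the root->tip path (root origination
    # excluded; these count changes since the last common ancestor)
    parents = tree.parent_map()
    per_species: dict[str, int] = {}
    for leaf in tree.root.leaves():
        total = 0
        node: Optional[TreeNode] = leaf
        while node is not None and parents[id(node)] is not None:
            total += len(report.branch_events.get(tree.node_id(node), []))
            node = parents[id(node)]
        per_species[leaf.label] = total
    return EventSummary(
        total_events=total_gains + total_losses,
        total_gains=total_gains, total_losses=total_losses,
        families_single_recruitment=single,
        families_convergent_recruitment=convergent,
        families_convergent_loss=convergent_loss,
        within_order_events=within, stem_events=stem,
        per_species_event_totals=per_species)


def lineage_deltas(report: EvolutionReport, from_node: str,
                   to_node: str) -> tuple[list[str], list[str]]:
    """Net (gains, losses) along the path from an ancestor to a descendant."""
    tree = report.tree
    start = tree.node_by_id(from_node)
    end = tree.node_by_id(to_node)
    parents = tree.parent_map()
    path: list[str] = []
    node: Optional[TreeNode] = end
    while node is not None and node is not start:
        path.append(tree.node_id(node))
        node = parents[id(node)]
    if node is not start:
        raise ValueError(f"{from_node!r} is not an ancestor of {to_node!r}")
    gains: list[str] = []
    losses: list[str] = []
    for branch in reversed(path):
        for fam, kind in report.branch_events.get(branch, []):
            if branch == tree.node_id(tree.root):
                continue  # root origination is not a path event
            (gains if kind == "gain" else losses).append(fam)
    # cocktail identity check: replay the path events stepwise
    current = report.cocktail(from_node)
    for branch in reversed(path):
        for fam, kind in report.branch_events.get(branch, []):
            if branch == tree.node_id(tree.root):
                continue
            if kind == "gain":
                current = current | {fam}
            else:
                current = current - {fam}
    assert current == report.cocktail(to_node), \
        "path events do not replay the cocktail"
    return gains, losses


def convention_grid(matrix: RepertoireMatrix, tree: SpeciesTree,
                    taxonomy: dict[str, str],
                    overrides: Optional[list[OverrideRecord]] = None,
                    methods: tuple[str, ...] = ("ACCTRAN", "DELTRAN")
                    ) -> pd.DataFrame:
    """Event summaries under every reporting convention combination
    (method x root-origination counting)."""
    rows = []
    for method in methods:
        for root_origin in (True, False):
            rep = reconstruct_venom_evolution(
                matrix, tree, method, overrides=overrides,
                count_root_origin=root_origin)
            s = summarize_events(rep, taxonomy)
            rows.append({"method": method, "count_root_origin": root_origin,
                         "total_events": s.total_events,
                         "gains": s.total_gains, "losses": s.total_losses,
                         "within_order": s.within_order_events,
                         "stem": s.stem_events,
                         "single_recruitment": s.n_single,
                         "convergent_recruitment": s.n_convergent})
    return pd.DataFrame(rows)
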