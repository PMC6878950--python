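"""Synthetic data with full ground truth.

Two generators emulate the statistical structure the analyses assume:

* :func:`simulate_matrix` evolves independent binary toxin-family
  characters down a species tree under per-branch gain/loss
  probabilities (the canonical species tree has no meaningful branch
  lengths, so probabilities are per branch, not rate x length), logging
  every event and every ancestral state;
* :func:`simulate_gene_tree` runs a birth-death process of gene lineages
  inside the species tree (per-branch duplication and loss
  probabilities), emitting a gene tree with per-leaf proteome flags and
  the true duplication placements.

:func:`paper_like_preset` fixes the generator at the study's scale: 93
families on the nine-species tree, rates chosen so that ancestral
repertoires are small and most families end up confined to a single
order, mirroring the sharing-spectrum shape of real repertoire data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trees import TreeNode
from .species import SpeciesTree, canonical_species_tree
from .matrix import RepertoireMatrix
from .reconcile import AnnotatedGeneTree

__all__ = [
    "SimulationTruth",
    "simulate_matrix",
    "simulate_gene_tree",
    "paper_like_preset",
    "random_topology",
    "PRESET_GAIN_RATE",
    "PRESET_LOSS_RATE",
    "PRESET_ROOT_PRESENCE",
    "PRESET_N_FAMILIES",
]

PRESET_GAIN_RATE = 0.06
PRESET_LOSS_RATE = 0.08
PRESET_ROOT_PRESENCE = 0.05
PRESET_N_FAMILIES = 93


@dataclass
class SimulationTruth:
    """Ground truth of a matrix simulation.

    ``true_events``: branch (child-node id) -> list of (family, gain|loss).
    ``true_node_states``: node id -> set of present families.
    """

    true_events: dict[str, list[tuple[str, str]]]
    true_node_states: dict[str, set[str]]
    parameters: dict[str, float | int]

    def events_for(self, family: str) -> list[tuple[str, str]]:
        return [(branch, kind) for branch, evs in self.true_events.items()
                for fam, kind in evs if fam == family]

    def replay(self, tree: SpeciesTree) -> pd.DataFrame:
        """Re-derive the tip matrix from root states + events (invariant:
        must equal the emitted matrix exactly)."""
        families = sorted({f for evs in self.true_events.values()
                           for f, _ in evs}
                          | self.true_node_states[tree.node_id(tree.root)])
        state = {f: (f in self.true_node_states[tree.node_id(tree.root)])
                 for f in families}
        tips: dict[str, dict[str, int]] = {}

        def walk(node: TreeNode, state: dict[str, bool]) -> None:
            if node.is_leaf:
                tips[node.label] = {f: int(v) for f, v in state.items()}
                return
            for child in node.children:
                child_state = dict(state)
                for fam, kind in self.true_events.get(
                        tree.node_id(child), []):
                    child_state[fam] = kind == "gain"
                walk(child, child_state)

        walk(tree.root, state)
        return pd.DataFrame(tips).reindex(families)


def simulate_matrix(tree: SpeciesTree, gain_rate: float, loss_rate: float,
                    n_families: int, root_presence_prob: float,
                    seed: int, max_resim: int = 1000
                    ) -> tuple[RepertoireMatrix, SimulationTruth]:
    """Independent per-branch gain/loss evolution of binary families.

    Families absent from every tip are discarded and re-simulated, so the
    emitted matrix satisfies the every-family-present-somewhere invariant.
    Same seed, same output.
    """
    for p, name in ((gain_rate, "gain_rate"), (loss_rate, "loss_rate"),
                    (root_presence_prob, "root_presence_prob")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    events: dict[str, list[tuple[str, str]]] = {}
    node_states: dict[str, set[str]] = {
        tree.node_id(n): set() for n in tree.root.postorder()}
    tip_rows: dict[str, dict[str, int]] = {}

    for k in range(n_families):
        fam = f"FAM{k + 1:03d}"
        for attempt in range(max_resim):
            fam_events: list[tuple[str, str]] = []
            fam_states: dict[str, bool] = {}
            root_present = bool(rng.random() < root_presence_prob)

            def walk(node: TreeNode, present: bool) -> None:
                fam_states[tree.node_id(node)] = present
                for child in node.children:
                    state = present
                    if present:
                        if rng.random() < loss_rate:
                            state = False
                            fam_events.append((tree.node_id(child), "loss"))
                    else:
                        if rng.random() < gain_rate:
                            state = True
                            fam_events.append((tree.node_id(child), "gain"))
                    walk(child, state)

            walk(tree.root, root_present)
            if any(fam_states[l.label] for l in tree.root.leaves()):
                break
        else:
            raise RuntimeError(
                f"family {fam} never present at any tip after "
                f"{max_resim} attempts; raise the rates")
        for node_id, present in fam_states.items():
            if present:
                node_states[node_id].add(fam)
        for branch, kind in fam_events:
            events.setdefault(branch, []).append((fam, kind))
        tip_rows[fam] = {l.label: int(fam_states[l.label])
                         for l in tree.root.leaves()}

    data = pd.DataFrame(tip_rows).T.astype(float)
    data = data[[l.label for l in tree.root.leaves()]]
    matrix = RepertoireMatrix(data=data, source="proteome")
    truth = SimulationTruth(
        true_events=events, true_node_states=node_states,
        parameters={"gain_rate": gain_rate, "loss_rate": loss_rate,
                    "root_presence_prob": root_presence_prob,
                    "n_families": n_families, "seed": seed})
    return matrix, truth


def paper_like_preset(seed: int) -> tuple[RepertoireMatrix, SimulationTruth]:
    """93 families on the canonical nine-species tree, rates fixed so the
    sharing spectrum is dominated by single-order families and the root
    repertoire is a small cocktail."""
    tree = canonical_species_tree()
    return simulate_matrix(
        tree, gain_rate=PRESET_GAIN_RATE, loss_rate=PRESET_LOSS_RATE,
        n_families=PRESET_N_FAMILIES,
        root_presence_prob=PRESET_ROOT_PRESENCE, seed=seed)


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def simulate_gene_tree(species_tree: SpeciesTree, duplication_rate: float,
                       gene_loss_rate: float, proteome_flag_prob: float,
                       seed: int, family: str = "SIMFAM",
                       max_retries: int = 100
                       ) -> tuple[AnnotatedGeneTree, list[str]]:
    """Birth-death of gene lineages inside the species tree.

    Per species-tree branch, each gene lineage duplicates at most once
    with probability ``duplication_rate`` and each resulting lineage is
    lost with probability ``gene_loss_rate``.  Returns the gene tree
    (leaves ``<species>_g<i>``, proteome-flagged with
    ``proteome_flag_prob``) and the true duplication placements as
    species-tree node ids (the child end of the branch the duplication
    occurred on).  Re-simulates on total extinction, up to a retry cap.
    """
    for p, name in ((duplication_rate, "duplication_rate"),
                    (gene_loss_rate, "gene_loss_rate"),
                    (proteome_flag_prob, "proteome_flag_prob")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a probability, got {p}")
    rng = np.random.default_rng(seed)

    for attempt in range(max_retries):
        counter = [0]
        duplications: list[str] = []

        def descend(node: TreeNode) -> Optional[TreeNode]:
            """Gene subtree of one lineage arriving (alive) at species node."""
            if node.is_leaf:
                counter[0] += 1
                return TreeNode(label=f"{node.label}_g{counter[0]}")
            parts = []
            for child in node.children:
                sub = into_branch(child)
                if sub is not None:
                    parts.append(sub)
            if not parts:
                return None
            if len(parts) == 1:
                return parts[0]
            return TreeNode(children=parts)

        def into_branch(sp_child: TreeNode) -> Optional[TreeNode]:
            """One lineage entering the branch that leads to sp_child."""
            lineages = 1
            duplicated = rng.random() < duplication_rate
            if duplicated:
                lineages = 2
            survivors = [rng.random() >= gene_loss_rate
                         for _ in range(lineages)]
            subtrees = [descend(sp_child) if alive else None
                        for alive in survivors]
            subtrees = [s for s in subtrees if s is not None]
            if duplicated and len(subtrees) == 2:
                duplications.append(species_tree.node_id(sp_child))
                return TreeNode(children=subtrees)
            if subtrees:
                return subtrees[0]
            return None

        root_tree = descend(species_tree.root)
        if root_tree is not None and not root_tree.is_leaf:
            break
        if root_tree is not None and root_tree.is_leaf:
            break
    else:
        raise RuntimeError(
            f"all gene lineages went extinct in {max_retries} simulations")

    flags = {l.label: bool(rng.random() < proteome_flag_prob)
             for l in root_tree.leaves()}
    annotated = AnnotatedGeneTree(tree=root_tree, proteome_flags=flags,
                                  outgroup_flags={}, family=family)
    return annotated, duplications


# ---------------------------------------------------------------------------
# Random trees (round-trip and property tests)
# ---------------------------------------------------------------------------

def random_topology(n_leaves: int, seed: int, with_lengths: bool = False,
                    with_supports: bool = False) -> TreeNode:
    """Uniform random binary topology over leaves L1..Ln, optionally with
    branch lengths and bootstrap supports."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(label=f"L{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    root = nodes[0]
    if with_lengths or with_supports:
        for node in root.postorder():
            if node is root:
                continue
            if with_lengths:
                node.length = float(np.round(rng.uniform(0.05, 2.0), 4))
            if with_supports and not node.is_leaf:
                node.support = float(int(rng.integers(0, 101)))
    return root
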