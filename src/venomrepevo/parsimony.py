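"""Small-parsimony machinery for binary presence/absence characters.

Given a fixed rooted species tree and one binary character (a toxin
family's presence across species), this module computes:

* the Fitch parsimony length, generalized to polytomies with Hartigan's
  majority-vote downpass;
* the complete set of most parsimonious reconstructions (MPRs) by
  exhaustive enumeration (the test oracle, guarded to small trees);
* ACCTRAN and DELTRAN event optimizations, operationalized as MPR
  selection.  Both first minimize the number of state changes (so the
  result is always an MPR).  ACCTRAN then minimizes the number of
  independent origins — branch gains plus one origin for a present root,
  since a family present at the root was recruited on the stem — and
  finally the number of losses; a single early recruitment followed by
  losses is preferred over convergent recruitments, but a root-state
  recruitment is never free, so a family in two distant clades resolves
  to convergent gains rather than a stem recruitment plus a compensating
  loss.  DELTRAN orders the same three criteria as changes, then losses,
  then origins (convergent shallow recruitments preferred).  Residual
  ties are broken deterministically toward presence (ACCTRAN) or absence
  (DELTRAN) in preorder, so deeper nodes get the preferred state first.

Whether the root origination appears as an event in the output is a
separate reporting convention (``count_root_origin``); the origin count
inside the selection criterion always includes the root.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .trees import TreeNode
from .species import SpeciesTree

__all__ = [
    "CharacterReconstruction",
    "MprSet",
    "OverrideRecord",
    "fitch_length",
    "enumerate_mprs",
    "optimize_character",
    "apply_overrides",
    "load_overrides",
    "save_overrides",
]

ACCTRAN = "ACCTRAN"
DELTRAN = "DELTRAN"

Character = dict[str, Optional[int]]
TreeLike = Union[TreeNode, SpeciesTree]


def _resolve(tree: TreeLike) -> tuple[TreeNode, dict[int, str]]:
    """Root node plus stable node-id map (leaf label / clade label /
    node<postorder index>)."""
    if isinstance(tree, SpeciesTree):
        return tree.root, dict(tree.node_ids)
    ids: dict[int, str] = {}
    used: set[str] = set()
    for i, node in enumerate(tree.postorder()):
        name = node.label or f"node{i}"
        if name in used:
            name = f"{name}_{i}"
        used.add(name)
        ids[id(node)] = name
    return tree, ids


def _leaf_states(root: TreeNode, character: Character) -> dict[int, Optional[int]]:
    states: dict[int, Optional[int]] = {}
    for leaf in root.leaves():
        if leaf.label not in character:
            raise KeyError(f"leaf {leaf.label!r} missing from character map")
        states[id(leaf)] = character[leaf.label]
    return states


# ---------------------------------------------------------------------------
# Fitch / Hartigan length
# ---------------------------------------------------------------------------

def fitch_length(tree: TreeLike, character: Character) -> int:
    """Minimal number of state changes (Hartigan downpass; ? = {0,1})."""
    root, _ = _resolve(tree)
    leaf_states = _leaf_states(root, character)

    def down(node: TreeNode) -> tuple[frozenset[int], int]:
        if node.is_leaf:
            s = leaf_states[id(node)]
            return (frozenset((0, 1)) if s is None else frozenset((s,))), 0
        sets_costs = [down(c) for c in node.children]
        cost = sum(c for _, c in sets_costs)
        votes = {0: sum(1 for s, _ in sets_costs if 0 in s),
                 1: sum(1 for s, _ in sets_costs if 1 in s)}
        top = max(votes.values())
        states = frozenset(s for s, v in votes.items() if v == top)
        return states, cost + len(node.children) - top

    return down(root)[1]


# ---------------------------------------------------------------------------
# Exhaustive MPR enumeration (oracle)
# ---------------------------------------------------------------------------

@dataclass
class MprSet:
    """All minimum-change internal-node state assignments for a character."""

    assignments: list[dict[str, int]]
    length: int

    def __contains__(self, internal_states: dict[str, int]) -> bool:
        return any(a == internal_states for a in self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)


def enumerate_mprs(tree: TreeLike, character: Character,
                   max_internal: int = 20) -> MprSet:
    """Enumerate every internal assignment achieving the Fitch length.

    Unknown (?) leaves contribute no cost (they can always copy their
    parent).  Exhaustive: guarded to ``max_internal`` internal nodes.
    """
    root, ids = _resolve(tree)
    leaf_states = _leaf_states(root, character)
    internals = [n for n in root.postorder() if not n.is_leaf]
    if len(internals) > max_internal:
        raise ValueError(
            f"{len(internals)} internal nodes exceeds the exhaustive-"
            f"enumeration guard ({max_internal}); this oracle is for tests")

    parents: dict[int, TreeNode] = {}
    for node in root.preorder():
        for child in node.children:
            parents[id(child)] = node

    def changes(assign: dict[int, int]) -> int:
        total = 0
        for node in root.postorder():
            if node is root:
                continue
            parent_state = assign[id(parents[id(node)])]
            if node.is_leaf:
                s = leaf_states[id(node)]
                if s is not None and s != parent_state:
                    total += 1
            elif assign[id(node)] != parent_state:
                total += 1
        return total

    best = None
    hits: list[dict[str, int]] = []
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        c = changes(assign)
        if best is None or c < best:
            best = c
            hits = [{ids[id(n)]: s for n, s in zip(internals, combo)}]
        elif c == best:
            hits.append({ids[id(n)]: s for n, s in zip(internals, combo)})
    assert best is not None
    return MprSet(assignments=hits, length=best)


# ---------------------------------------------------------------------------
# ACCTRAN / DELTRAN optimization
# ---------------------------------------------------------------------------

@dataclass
class CharacterReconstruction:
    """One family's ancestral states and gain/loss events under one rule.

    ``node_states`` maps node id -> 0/1 (None for unscored ? leaves);
    ``events`` lists (branch child-node id, "gain"|"loss"); the root-
    origination recruitment, when counted, sits on the root's own id.
    ``length`` is the Fitch change count (root origination excluded).
    """

    family: str
    method: str
    node_states: dict[str, Optional[int]]
    events: list[tuple[str, str]]
    length: int
    count_root_origin: bool = True
    # references kept so overrides can re-optimize the same inputs
    _tree: Optional[TreeNode] = field(default=None, repr=False)
    _ids: Optional[dict[int, str]] = field(default=None, repr=False)
    _character: Optional[Character] = field(default=None, repr=False)

    @property
    def gains(self) -> int:
        return sum(1 for _, kind in self.events if kind == "gain")

    @property
    def losses(self) -> int:
        return sum(1 for _, kind in self.events if kind == "loss")

    def internal_states(self) -> dict[str, int]:
        leaves = {n.label for n in self._tree.leaves()} if self._tree else set()
        return {k: v for k, v in self.node_states.items()
                if v is not None and k not in leaves}


def _edge_cost(method: str, s: int, t: int) -> tuple[int, int, int]:
    """(changes, primary, secondary) for a parent s -> child t edge.

    Primary/secondary are (origins, losses) for ACCTRAN and
    (losses, origins) for DELTRAN; triples add componentwise and compare
    lexicographically, which distributes over the independent subtrees.
    """
    if s == t:
        return (0, 0, 0)
    if t == 1:  # gain (one origin)
        return (1, 1, 0) if method == ACCTRAN else (1, 0, 1)
    return (1, 0, 1) if method == ACCTRAN else (1, 1, 0)  # loss


def _root_origin_cost(method: str) -> tuple[int, int, int]:
    """A present root counts as one origin in the selection criterion."""
    return (0, 1, 0) if method == ACCTRAN else (0, 0, 1)


def _add(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(x + y for x, y in zip(a, b))


def _optimize(root: TreeNode, ids: dict[int, str], character: Character,
              method: str, pins: Optional[dict[str, int]] = None,
              origin_count: Optional[int] = None,
              count_root_origin: bool = True,
              family: str = "") -> CharacterReconstruction:
    """Shared constrained optimizer behind optimize_character/apply_overrides.

    ``pins`` restricts named nodes to a fixed state.  ``origin_count``
    requires exactly that many origins (edge gains plus a present root),
    minimizing changes subject to the constraint; the method's secondary
    criterion and tie preference still order the remaining freedom.
    """
    if method not in (ACCTRAN, DELTRAN):
        raise ValueError(f"method must be ACCTRAN or DELTRAN, got {method!r}")
    pins = pins or {}
    known = {ids[id(n)] for n in root.postorder()}
    bad = [p for p in pins if p not in known]
    if bad:
        raise ValueError(f"pinned nodes not in tree: {bad}")
    leaf_states = _leaf_states(root, character)
    prefer = 1 if method == ACCTRAN else 0
    track_g = origin_count is not None
    gmax = (origin_count if track_g else 0) or 0

    # cost[node][state] -> {gains_in_subtree: (changes, primary, secondary)}
    cost: dict[int, dict[int, dict[int, tuple[int, int, int]]]] = {}

    def allowed(node: TreeNode) -> tuple[int, ...]:
        nid = ids[id(node)]
        if nid in pins:
            return (pins[nid],)
        if node.is_leaf:
            s = leaf_states[id(node)]
            return (0, 1) if s is None else (s,)
        return (0, 1)

    def down(node: TreeNode) -> None:
        for c in node.children:
            down(c)
        table: dict[int, dict[int, tuple[int, int, int]]] = {}
        for s in allowed(node):
            if node.is_leaf:
                table[s] = {0: (0, 0, 0)}
                continue
            acc: dict[int, tuple[int, int, int]] = {0: (0, 0, 0)}
            for child in node.children:
                nxt: dict[int, tuple[int, int, int]] = {}
                for t, sub in cost[id(child)].items():
                    ec = _edge_cost(method, s, t)
                    eg = 1 if (track_g and t == 1 and s == 0) else 0
                    for gc, cc in sub.items():
                        for ga, ca in acc.items():
                            g = ga + gc + eg
                            if track_g and g > gmax:
                                continue
                            tot = _add(_add(ca, cc), ec)
                            if g not in nxt or tot < nxt[g]:
                                nxt[g] = tot
                if not nxt:
                    acc = {}
                    break
                acc = nxt
            if acc:
                table[s] = acc
        cost[id(node)] = table

    down(root)

    # pick the root state (and, when constrained, the exact origin count):
    # optimality (lexicographic cost vector, a present root adding one
    # origin) first, then the method's state preference, then the
    # smallest subtree gain count
    best: Optional[tuple[tuple[int, int, int], int, int, int]] = None
    for s, sub in cost[id(root)].items():
        for g, vec in sub.items():
            if track_g and g + (1 if s == 1 else 0) != origin_count:
                continue
            if s == 1:
                vec = _add(vec, _root_origin_cost(method))
            cand = (vec, 0 if s == prefer else 1, g, s)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        detail = (f"origin count {origin_count}" if track_g
                  else f"pins {pins}")
        raise ValueError(
            f"no reconstruction satisfies the constraints ({detail})")

    assign: dict[int, int] = {}

    def _child_options(child: TreeNode, state: int):
        """(child state, child-subtree gains, combined cost, edge gain)."""
        for t, sub in cost[id(child)].items():
            ec = _edge_cost(method, state, t)
            eg = 1 if (track_g and t == 1 and state == 0) else 0
            for gc, cc in sub.items():
                yield t, gc, _add(cc, ec), eg

    def up(node: TreeNode, state: int, budget: int) -> None:
        assign[id(node)] = state
        if node.is_leaf:
            return
        kids = node.children
        # suffix DP: suf[j][g] = min cost pair over kids[j:] using g gains
        suf: list[dict[int, tuple[int, int, int]]] = [{} for _ in range(len(kids) + 1)]
        suf[len(kids)] = {0: (0, 0, 0)}
        for j in range(len(kids) - 1, -1, -1):
            for t, gc, pair, eg in _child_options(kids[j], state):
                for g_rest, c_rest in suf[j + 1].items():
                    g = gc + eg + g_rest
                    if track_g and g > budget:
                        continue
                    tot = _add(pair, c_rest)
                    if g not in suf[j] or tot < suf[j][g]:
                        suf[j][g] = tot
        left = budget if track_g else 0
        for j, child in enumerate(kids):
            target = suf[j][left]
            opts = sorted(_child_options(child, state),
                          key=lambda o: (0 if o[0] == prefer else 1, o[2], o[1]))
            for t, gc, pair, eg in opts:
                rest = left - gc - eg if track_g else 0
                if rest < 0 or rest not in suf[j + 1]:
                    continue
                if _add(pair, suf[j + 1][rest]) == target:
                    up(child, t, gc)
                    left = rest if track_g else 0
                    break
            else:  # pragma: no cover - DP and backtrace disagree
                raise AssertionError("backtrace failed to meet its own bound")

    up(root, best[3], best[2])

    node_states: dict[str, Optional[int]] = {}
    for node in root.postorder():
        nid = ids[id(node)]
        if node.is_leaf and leaf_states[id(node)] is None:
            node_states[nid] = None  # unscored
        else:
            node_states[nid] = assign[id(node)]

    events: list[tuple[str, str]] = []
    length = 0
    for node in root.preorder():
        for child in node.children:
            if child.is_leaf and leaf_states[id(child)] is None:
                continue
            s, t = assign[id(node)], assign[id(child)]
            if s != t:
                events.append((ids[id(child)], "gain" if t == 1 else "loss"))
                length += 1
    if count_root_origin and assign[id(root)] == 1:
        events.insert(0, (ids[id(root)], "gain"))

    return CharacterReconstruction(
        family=family, method=method, node_states=node_states,
        events=events, length=length, count_root_origin=count_root_origin,
        _tree=root, _ids=ids, _character=dict(character))


def optimize_character(tree: TreeLike, character: Character, method: str,
                       count_root_origin: bool = True,
                       family: str = "") -> CharacterReconstruction:
    """ACCTRAN or DELTRAN event optimization of one binary character."""
    root, ids = _resolve(tree)
    return _optimize(root, ids, character, method,
                     count_root_origin=count_root_origin, family=family)


# ---------------------------------------------------------------------------
# Overrides (gene-tree-informed adjustments)
# ---------------------------------------------------------------------------

@dataclass
class OverrideRecord:
    """Gene-tree-derived constraint on a family's event optimization.

    kind "single_origin": exactly one recruitment (a deep gain, or a
    present root).  kind "multi_origin": exactly ``count`` recruitments.
    kind "pin_state": payload (node id, state) fixes one node.
    """

    family: str
    kind: str  # single_origin | multi_origin | pin_state
    count: Optional[int] = None
    node: Optional[str] = None
    state: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "single_origin":
            self.count = 1
        elif self.kind == "multi_origin":
            if not self.count or self.count < 1:
                raise ValueError("multi_origin override needs count >= 1")
        elif self.kind == "pin_state":
            if self.node is None or self.state not in (0, 1):
                raise ValueError("pin_state override needs node and state 0/1")
        else:
            raise ValueError(f"unknown override kind: {self.kind!r}")


def apply_overrides(recon: CharacterReconstruction,
                    overrides: list[OverrideRecord]) -> CharacterReconstruction:
    """Re-optimize a reconstruction under its family's overrides.

    The result is minimal-change among constraint-satisfying assignments;
    the original method's secondary criterion and tie-breaks still apply.
    An empty or non-matching override list returns the input unchanged.
    """
    relevant = [o for o in overrides if o.family == recon.family]
    if not relevant:
        return recon
    if recon._tree is None:
        raise ValueError("reconstruction lacks its input references")
    pins: dict[str, int] = {}
    origin_count: Optional[int] = None
    for o in relevant:
        if o.kind == "pin_state":
            if o.node in pins and pins[o.node] != o.state:
                raise ValueError(
                    f"conflicting pins for node {o.node!r} "
                    f"(family {recon.family!r})")
            pins[o.node] = o.state
        else:
            if origin_count is not None and origin_count != o.count:
                raise ValueError(
                    f"conflicting origin counts for family {recon.family!r}")
            origin_count = o.count
    return _optimize(recon._tree, recon._ids, recon._character, recon.method,
                     pins=pins, origin_count=origin_count,
                     count_root_origin=recon.count_root_origin,
                     family=recon.family)


def load_overrides(source: str) -> list[OverrideRecord]:
    """Read override records from a YAML file (one mapping per family)."""
    with open(source) as fh:
        raw = yaml.safe_load(fh) or []
    out = []
    for rec in raw:
        out.append(OverrideRecord(
            family=rec["family"], kind=rec["kind"], count=rec.get("count"),
            node=rec.get("node"), state=rec.get("state")))
    return out


def save_overrides(records: list[OverrideRecord], dest: str) -> None:
    raw = []
    for r in records:
        entry: dict = {"family": r.family, "kind": r.kind}
        if r.kind == "multi_origin":
            entry["count"] = r.count
        if r.kind == "pin_state":
            entry["node"] = r.node
            entry["state"] = r.state
        raw.append(entry)
    with open(dest, "w") as fh:
        yaml.safe_dump(raw, fh, allow_unicode=True, sort_keys=False)
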