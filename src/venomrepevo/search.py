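"""Exact maximum-parsimony tree search by branch and bound.

Searches all unrooted binary topologies for the minimum total Fitch
length over the characters of a presence/absence matrix (equal weights).
Trees are grown by stepwise taxon insertion; since parsimony length is
monotone under taxon addition, any partial tree longer than the current
upper bound is pruned with all of its completions.  The search is exact:
the returned set is the complete set of minimum-length topologies.

Character state sets are packed into two big integers per node (one bit
per character for "can be absent" / "can be present"), so the Fitch pass
over all characters is a handful of bitwise operations per node.
"""

from __future__ import annotations

from dataclasses import dataclass

from .matrix import RepertoireMatrix
from .trees import TreeNode, parse_newick, bipartitions

__all__ = ["SearchResult", "branch_and_bound_search", "exhaustive_search",
           "strict_consensus", "tree_length"]

# A tree over taxon indices 1..n-1, viewed as rooted at pendant taxon 0:
# leaf = int, internal = (left, right).


@dataclass
class SearchResult:
    best_length: int
    mp_trees: list[TreeNode]
    explored: int

    @property
    def newicks(self) -> list[str]:
        from .trees import to_newick
        return [to_newick(t, include_lengths=False) for t in self.mp_trees]


def _encode(matrix: RepertoireMatrix) -> tuple[list[str], list[int], list[int], int]:
    """Per-taxon bitmasks m0 (absent possible) and m1 (present possible)."""
    taxa = matrix.species
    nchar = len(matrix.families)
    full = (1 << nchar) - 1
    m0 = [0] * len(taxa)
    m1 = [0] * len(taxa)
    for j, fam in enumerate(matrix.families):
        row = matrix.data.loc[fam]
        for i, sp in enumerate(taxa):
            v = row[sp]
            if v != v:  # NaN: unknown -> full state set
                m0[i] |= 1 << j
                m1[i] |= 1 << j
            elif v == 0:
                m0[i] |= 1 << j
            else:
                m1[i] |= 1 << j
    return taxa, m0, m1, full


def _fitch(tree, m0, m1, full) -> tuple[int, int, int]:
    """(state0, state1, length) of a subtree (leaf int or (l, r) tuple)."""
    if isinstance(tree, int):
        return m0[tree], m1[tree], 0
    l0, l1, ll = _fitch(tree[0], m0, m1, full)
    r0, r1, rl = _fitch(tree[1], m0, m1, full)
    i0, i1 = l0 & r0, l1 & r1
    conflict = full & ~(i0 | i1)
    s0 = i0 | (conflict & (l0 | r0))
    s1 = i1 | (conflict & (l1 | r1))
    return s0, s1, ll + rl + conflict.bit_count()


def _length(tree, anchor: int, m0, m1, full) -> int:
    """Length of the unrooted tree = subtree rooted against pendant anchor."""
    s0, s1, ln = _fitch(tree, m0, m1, full)
    conflict = full & ~((s0 & m0[anchor]) | (s1 & m1[anchor]))
    return ln + conflict.bit_count()


def _insertions(tree, taxon: int):
    """All trees obtained by inserting ``taxon`` on each edge of ``tree``
    (including the edge to the anchor pendant)."""
    yield (tree, taxon)
    if isinstance(tree, int):
        return
    for sub in _insertions(tree[0], taxon):
        yield (sub, tree[1])
    for sub in _insertions(tree[1], taxon):
        yield (tree[0], sub)


def _splits(tree, anchor: int, n: int) -> frozenset[frozenset[int]]:
    """Canonical unrooted topology identity: the set of non-trivial splits,
    each as the frozenset of taxon indices not containing the anchor."""
    out: set[frozenset[int]] = set()

    def visit(t) -> frozenset[int]:
        if isinstance(t, int):
            return frozenset((t,))
        below = visit(t[0]) | visit(t[1])
        if 1 < len(below) < n - 1:
            out.add(below)
        return below

    visit(tree)
    return frozenset(out)


def _addition_order(matrix: RepertoireMatrix) -> list[int]:
    """Taxa in decreasing character-conflict order (sum of pairwise
    disagreements with all other taxa); ties by input order."""
    data = (matrix.data == 1).astype(int).to_numpy()
    unknown = matrix.data.isna().to_numpy()
    n = data.shape[1]
    conflict = [0] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            both = ~(unknown[:, i] | unknown[:, j])
            conflict[i] += int((data[both, i] != data[both, j]).sum())
    return sorted(range(n), key=lambda i: (-conflict[i], i))


def _greedy_tree(order, m0, m1, full):
    tree = (order[1], order[2])
    for taxon in order[3:]:
        tree = min(_insertions(tree, taxon),
                   key=lambda t: _length(t, order[0], m0, m1, full))
    return tree


def _to_treenode(tree, anchor: int, taxa: list[str]) -> TreeNode:
    def build(t) -> TreeNode:
        if isinstance(t, int):
            return TreeNode(label=taxa[t])
        return TreeNode(children=[build(t[0]), build(t[1])])

    return TreeNode(children=[TreeNode(label=taxa[anchor]), build(tree)])


def branch_and_bound_search(matrix: RepertoireMatrix) -> SearchResult:
    """Exact search for all minimum-length unrooted binary topologies."""
    taxa, m0, m1, full = _encode(matrix)
    n = len(taxa)
    if n < 3:
        raise ValueError("tree search needs at least 3 species")
    order = _addition_order(matrix)
    anchor = order[0]
    if n == 3:
        tree = (order[1], order[2])
        return SearchResult(
            best_length=_length(tree, anchor, m0, m1, full),
            mp_trees=[_to_treenode(tree, anchor, taxa)], explored=1)

    best = _length(_greedy_tree(order, m0, m1, full), anchor, m0, m1, full)
    hits: dict[frozenset, tuple] = {}
    explored = 0

    def dfs(tree, level: int) -> None:
        nonlocal best, explored, hits
        explored += 1
        ln = _length(tree, anchor, m0, m1, full)
        if ln > best:
            return
        if level == n:
            if ln < best:
                best = ln
                hits = {}
            hits[_splits(tree, anchor, n)] = tree
            return
        for nxt in _insertions(tree, order[level]):
            dfs(nxt, level + 1)

    dfs((order[1], order[2]), 3)
    # drop trees that beat the greedy bound early but not the final best
    mp = [_to_treenode(t, anchor, taxa) for s, t in sorted(
        hits.items(), key=lambda kv: sorted(map(sorted, kv[0])))
        if _length(t, anchor, m0, m1, full) == best]
    return SearchResult(best_length=best, mp_trees=mp, explored=explored)


def exhaustive_search(matrix: RepertoireMatrix,
                      max_taxa: int = 8) -> SearchResult:
    """Enumerate every unrooted binary topology (test oracle, <= max_taxa)."""
    taxa, m0, m1, full = _encode(matrix)
    n = len(taxa)
    if n < 3:
        raise ValueError("tree search needs at least 3 species")
    if n > max_taxa:
        raise ValueError(f"{n} taxa exceeds the exhaustive guard ({max_taxa})")
    anchor = 0
    trees = [(1, 2)]
    for taxon in range(3, n):
        trees = [t for base in trees for t in _insertions(base, taxon)]
    best = None
    hits = []
    for t in trees:
        ln = _length(t, anchor, m0, m1, full)
        if best is None or ln < best:
            best, hits = ln, [t]
        elif ln == best:
            hits.append(t)
    return SearchResult(best_length=best,
                        mp_trees=[_to_treenode(t, anchor, taxa) for t in hits],
                        explored=len(trees))


def tree_length(tree: TreeNode, matrix: RepertoireMatrix) -> int:
    """Total Fitch length of an arbitrary (possibly multifurcating) tree."""
    from .parsimony import fitch_length
    total = 0
    for fam in matrix.families:
        total += fitch_length(tree, matrix.character(fam))
    return total


def strict_consensus(trees: list[TreeNode]) -> TreeNode:
    """Strict consensus: exactly the bipartitions present in every tree."""
    import dendropy
    from .trees import to_newick, leaf_labels, parse_newick as _parse

    if not trees:
        raise ValueError("no trees to summarize")
    leafsets = {frozenset(leaf_labels(t)) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees have mismatched leaf sets")
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(dendropy.Tree.get(
            data=to_newick(t, include_lengths=False), schema="newick",
            taxon_namespace=tns, preserve_underscores=True))
    cons = tl.consensus(min_freq=1.0)
    newick = cons.as_string(schema="newick", suppress_rooting=True,
                            suppress_edge_lengths=True,
                            unquoted_underscores=True)
    return _parse(newick)
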