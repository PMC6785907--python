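"""Maximum parsimony for unordered (Fitch) multistate characters.

Tree length is computed by Hartigan's generalization of the Fitch pass, so
multifurcating trees are scored exactly as given (no implicit resolution).
Searches emit binary unrooted trees: exact search by branch and bound with
max-min taxon addition, heuristic search by random-addition starts plus TBR
(tree bisection-reconnection) swapping, and clade support by character
bootstrap.  Ensemble fit indices follow the standard definitions

    CI = sum(m) / sum(s)      (consistency)
    RI = (sum(g) - sum(s)) / (sum(g) - sum(m))      (retention)
    HI = 1 - CI               (homoplasy)

with m the minimum conceivable steps of a character (observed states - 1),
s its steps on the tree, and g its maximum conceivable steps (taxa with an
observed state minus the largest state class); characters with g = m are
excluded from the RI sums.

Internally a search tree is an adjacency map over integer nodes (leaves
0..n-1, internal nodes above) and all characters are packed into
big-integer bitfields, so a full-tree Fitch pass is a short sequence of
bitwise operations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coding import CharacterMatrix
from .trees import Node, PhyloTree, strict_consensus, rf_distance  # noqa: F401

__all__ = [
    "CharacterFit", "SearchResult", "fitch_length", "character_fits",
    "ensemble_indices", "branch_and_bound_search", "tbr_heuristic_search",
    "bootstrap_support", "strict_consensus", "rf_distance",
]


@dataclass(frozen=True)
class CharacterFit:
    """Per-character m <= s <= g underlying the ensemble indices."""

    m: int
    s: int
    g: int

    def __post_init__(self):
        if not (0 <= self.m <= self.s <= self.g):
            raise ValueError(f"need 0 <= m <= s <= g, got {self}")


@dataclass
class SearchResult:
    trees: list[PhyloTree]
    score: int

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# scoring

def _column_sets(matrix: CharacterMatrix, j: int) -> dict[str, frozenset[int] | None]:
    return {t: None if s is None else frozenset([s])
            for t, s in matrix.column(j).items()}


def _min_max_steps(matrix: CharacterMatrix, j: int) -> tuple[int, int]:
    counts: dict[int, int] = {}
    for s in matrix.column(j).values():
        if s is not None:
            counts[s] = counts.get(s, 0) + 1
    if not counts:
        return 0, 0
    n_obs = sum(counts.values())
    return len(counts) - 1, n_obs - max(counts.values())


def _hartigan_steps(tree: PhyloTree, column: dict[str, frozenset[int] | None],
                    n_states: int) -> int:
    """Exact minimum state changes for one unordered character (Hartigan),
    valid for multifurcating trees; missing leaves carry the full state set."""
    full = frozenset(range(n_states))
    steps = 0

    def down(node: Node) -> frozenset[int]:
        nonlocal steps
        if node.is_leaf:
            s = column.get(node.label)
            return full if s is None else s
        sets = [down(c) for c in node.children]
        count: dict[int, int] = {}
        for s in sets:
            for st in s:
                count[st] = count.get(st, 0) + 1
        k = max(count.values())
        steps += len(sets) - k
        return frozenset(st for st, c in count.items() if c == k)

    root_set = down(tree.root)
    # an unrooted tree scored at an arbitrary root gives the same count
    del root_set
    return steps


def _check_leaves(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    tl, ml = set(tree.leaves), set(matrix.taxa)
    if tl != ml:
        raise ValueError(
            f"tree/matrix taxa differ; only in tree: {sorted(tl - ml)}, "
            f"only in matrix: {sorted(ml - tl)}")


def fitch_length(tree: PhyloTree, matrix: CharacterMatrix) -> tuple[int, list[int]]:
    """Parsimony length of ``tree`` and per-character steps.

    Accepts binary or multifurcating trees (polytomies are scored as hard).
    Length is a property of the unrooted shape, so any rooting of the same
    tree scores identically.
    """
    _check_leaves(tree, matrix)
    per_char = []
    for j in range(matrix.n_characters):
        n_states = len(matrix.characters[j].state_labels)
        per_char.append(_hartigan_steps(tree, _column_sets(matrix, j), n_states))
    return sum(per_char), per_char


def character_fits(tree: PhyloTree, matrix: CharacterMatrix) -> list[CharacterFit]:
    _, per_char = fitch_length(tree, matrix)
    fits = []
    for j, s in enumerate(per_char):
        m, g = _min_max_steps(matrix, j)
        fits.append(CharacterFit(m=m, s=s, g=g))
    return fits


@dataclass(frozen=True)
class EnsembleIndices:
    ci: float
    ri: float
    hi: float
    fits: tuple[CharacterFit, ...]


def ensemble_indices(tree: PhyloTree, matrix: CharacterMatrix) -> EnsembleIndices:
    fits = character_fits(tree, matrix)
    sum_s = sum(f.s for f in fits)
    if sum_s == 0:
        raise ValueError("all characters constant on this tree: CI undefined")
    ci = sum(f.m for f in fits) / sum_s
    ri_fits = [f for f in fits if f.g > f.m]
    denom = sum(f.g - f.m for f in ri_fits)
    ri = (sum(f.g - f.s for f in ri_fits) / denom) if denom else 1.0
    return EnsembleIndices(ci=ci, ri=ri, hi=1.0 - ci, fits=tuple(fits))


# ---------------------------------------------------------------------------
# fast internal representation for search

class _Encoded:
    """Characters packed into big-integer bitfields, one field per character.

    A node's candidate state set across all characters is a single Python
    int; Fitch intersection/union become bitwise ops, and empty fields (the
    union events) are counted with a shift-fold that isolates each field's
    low bit.  This keeps a full-tree Fitch pass in the tens of microseconds,
    which the swappers rely on.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.taxa = matrix.taxa
        self.n = len(self.taxa)
        self.n_chars = matrix.n_characters
        self.width = max((len(c.state_labels) for c in matrix.characters),
                         default=1)
        w = self.width
        self.low = 0          # 1 at each field's lowest bit
        for j in range(self.n_chars):
            self.low |= 1 << (j * w)
        self.fullf = (1 << w) - 1
        self.masks = []
        for i in range(self.n):
            acc = 0
            for j in range(self.n_chars):
                nst = len(matrix.characters[j].state_labels)
                s = matrix.states[i][j]
                field = (1 << nst) - 1 if s is None else (1 << s)
                acc |= field << (j * w)
            self.masks.append(acc)

    def empty_fields(self, x: int) -> int:
        """1 at the low bit of every all-zero field of x."""
        t = x
        for s in range(1, self.width):
            t |= x >> s
        return self.low & ~t


def _postorder(adj: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    """(node, parent) pairs, children before parents."""
    order, stack = [], [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for nb in adj[node]:
            if nb != parent:
                stack.append((nb, node))
    order.reverse()
    return order


def _score_adj(adj: dict[int, list[int]], enc: _Encoded) -> int:
    """Fitch length of a binary unrooted adjacency tree (packed bitfields)."""
    if enc.n_chars == 0:
        return 0
    # root at an internal node so every leaf state enters as a child set
    root = next((u for u in adj if len(adj[u]) > 1), next(iter(adj)))
    sets: dict[int, int] = {}
    steps = 0
    masks = enc.masks
    fullf = enc.fullf
    for node, parent in _postorder(adj, root):
        kids = [nb for nb in adj[node] if nb != parent]
        if not kids:
            sets[node] = masks[node]
            continue
        acc = sets[kids[0]]
        for k in kids[1:]:
            b = sets[k]
            inter = acc & b
            z = enc.empty_fields(inter)
            if z:
                steps += z.bit_count()
                acc = inter | ((acc | b) & (z * fullf))
            else:
                acc = inter
        sets[node] = acc
    return steps


def _adj_to_tree(adj: dict[int, list[int]], enc: _Encoded,
                 score: int | None = None) -> PhyloTree:
    n = enc.n
    if n == 1:
        return PhyloTree(Node(label=enc.taxa[0]), rooted=False, length=score)
    if n == 2:
        return PhyloTree(Node(children=[Node(label=enc.taxa[0]),
                                        Node(label=enc.taxa[1])]),
                         rooted=False, length=score)
    root = adj[0][0]  # internal neighbor of leaf 0

    def build(node: int, parent: int) -> Node:
        if node < n:
            return Node(label=enc.taxa[node])
        return Node(children=[build(nb, node) for nb in adj[node] if nb != parent])

    children = [build(nb, root) for nb in adj[root]]
    return PhyloTree(Node(children=children), rooted=False, length=score)


def _splits_sig(adj: dict[int, list[int]], n: int) -> frozenset:
    """Canonical signature: nontrivial splits as leaf bitsets not containing 0."""
    sig = set()
    root = adj[0][0]
    below: dict[int, int] = {}
    for node, parent in _postorder(adj, root):
        if node < n:
            below[node] = 1 << node
        else:
            below[node] = 0
            for nb in adj[node]:
                if nb != parent:
                    below[node] |= below[nb]
            m = below[node]
            if not (m & 1) and bin(m).count("1") >= 2 and node != root:
                sig.add(m)
    return frozenset(sig)


def _initial_triple(adj_out: dict[int, list[int]], a: int, b: int, c: int,
                    next_id: int) -> int:
    hub = next_id
    adj_out.clear()
    adj_out[hub] = [a, b, c]
    adj_out[a] = [hub]
    adj_out[b] = [hub]
    adj_out[c] = [hub]
    return hub


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return [(u, v) for u in adj for v in adj[u] if u < v]


def _attach_leaf(adj: dict[int, list[int]], leaf: int, edge: tuple[int, int],
                 new_internal: int) -> None:
    u, v = edge
    adj[u] = [new_internal if x == v else x for x in adj[u]]
    adj[v] = [new_internal if x == u else x for x in adj[v]]
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def _copy(adj: dict[int, list[int]]) -> dict[int, list[int]]:
    return {k: list(v) for k, v in adj.items()}


def _hamming(enc: _Encoded, i: int, j: int) -> int:
    return enc.empty_fields(enc.masks[i] & enc.masks[j]).bit_count()


def _addition_order(enc: _Encoded) -> list[int]:
    """Max-min distance insertion order (first three maximize spread)."""
    n = enc.n
    if n <= 3:
        return list(range(n))
    d = [[_hamming(enc, i, j) for j in range(n)] for i in range(n)]
    first = max(itertools.combinations(range(n), 3),
                key=lambda t: (d[t[0]][t[1]] + d[t[0]][t[2]] + d[t[1]][t[2]], [-x for x in t]))
    order = list(first)
    rest = [i for i in range(n) if i not in order]
    while rest:
        nxt = max(rest, key=lambda i: (min(d[i][j] for j in order), -i))
        order.append(nxt)
        rest.remove(nxt)
    return order


def _remaining_state_bound(enc: _Encoded, added: list[int], rest: list[int]) -> int:
    """States present only among unplaced taxa must each cost >= 1 step."""
    if not rest:
        return 0
    have = 0
    for i in added:
        have |= enc.masks[i]
    extra = 0
    for i in rest:
        m = enc.masks[i]
        # a taxon's (single-state) mask disjoint from everything seen so far
        extra += enc.empty_fields(m & have).bit_count()
        have |= m
    return extra


def branch_and_bound_search(matrix: CharacterMatrix, *,
                            taxon_cap: int = 18) -> SearchResult:
    """All minimum-length binary unrooted trees, by branch and bound.

    Taxa are inserted in max-min distance order; a partial tree is pruned
    when its length plus the count of states confined to unplaced taxa
    exceeds the best complete length found so far (both bounds are
    admissible, so the tree set is exactly the optimal set).
    """
    n = len(matrix.taxa)
    if n > taxon_cap:
        raise ValueError(
            f"{n} taxa exceeds the exact-search cap ({taxon_cap}); "
            "use tbr_heuristic_search")
    enc = _Encoded(matrix)
    if n <= 3:
        if n == 3:
            adj: dict[int, list[int]] = {}
            _initial_triple(adj, 0, 1, 2, 3)
            return SearchResult([_adj_to_tree(adj, enc, _score_adj(adj, enc))],
                                _score_adj(adj, enc))
        t = _adj_to_tree({0: [1], 1: [0]} if n == 2 else {0: []}, enc)
        t.length = 0
        return SearchResult([t], 0)

    order = _addition_order(enc)
    best_score = [None]  # type: list[int | None]
    best_trees: list[dict[int, list[int]]] = []

    adj: dict[int, list[int]] = {}
    _initial_triple(adj, order[0], order[1], order[2], n)

    def recurse(adj: dict[int, list[int]], depth: int, next_internal: int) -> None:
        score = _score_adj(adj, enc)
        added = order[:depth]
        rest = order[depth:]
        bound = score + _remaining_state_bound(enc, added, rest)
        if best_score[0] is not None and bound > best_score[0]:
            return
        if not rest:
            if best_score[0] is None or score < best_score[0]:
                best_score[0] = score
                best_trees.clear()
            if score == best_score[0]:
                best_trees.append(_copy(adj))
            return
        leaf = rest[0]
        for edge in _edges(adj):
            child = _copy(adj)
            _attach_leaf(child, leaf, edge, next_internal)
            recurse(child, depth + 1, next_internal + 1)

    recurse(adj, 3, n + 1)
    trees = [_adj_to_tree(a, enc, best_score[0]) for a in best_trees]
    trees.sort(key=lambda t: t.newick())
    return SearchResult(trees, best_score[0])


# ---------------------------------------------------------------------------
# TBR heuristic

def _component_nodes(adj: dict[int, list[int]], start: int, banned: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != banned and v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _suppress_degree2(adj: dict[int, list[int]], node: int) -> None:
    if len(adj.get(node, [])) == 2:
        a, b = adj.pop(node)
        adj[a] = [b if x == node else x for x in adj[a]]
        adj[b] = [a if x == node else x for x in adj[b]]


def _tbr_neighbors(adj: dict[int, list[int]], n: int):
    """Yield adjacency maps one TBR move away (includes SPR/NNI as cases)."""
    fresh = max(adj) + 1
    for (a, b) in _edges(adj):
        comp_a = _component_nodes(adj, a, b)
        comp_b = _component_nodes(adj, b, a)
        base = _copy(adj)
        base[a] = [x for x in base[a] if x != b]
        base[b] = [x for x in base[b] if x != a]
        _suppress_degree2(base, a)
        _suppress_degree2(base, b)
        sub_a = {u: [v for v in base[u]] for u in comp_a if u in base}
        sub_b = {u: [v for v in base[u]] for u in comp_b if u in base}
        ea = _edges(sub_a) or [None]
        eb = _edges(sub_b) or [None]
        for e1 in ea:
            for e2 in eb:
                new = {u: list(vs) for part in (sub_a, sub_b)
                       for u, vs in part.items()}
                ends = []
                for edge, nid in ((e1, fresh), (e2, fresh + 1)):
                    if edge is None:
                        continue
                    u, v = edge
                    new[u] = [nid if x == v else x for x in new[u]]
                    new[v] = [nid if x == u else x for x in new[v]]
                    new[nid] = [u, v]
                    ends.append(nid)
                if e1 is None:
                    ends.insert(0, next(iter(sub_a)))
                if e2 is None:
                    ends.append(next(iter(sub_b)))
                x, y = ends
                new[x] = new.get(x, []) + [y]
                new[y] = new.get(y, []) + [x]
                yield new


def _greedy_addition(enc: _Encoded, order: Sequence[int]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {}
    _initial_triple(adj, order[0], order[1], order[2], enc.n)
    nxt = enc.n + 1
    for leaf in order[3:]:
        best, best_adj = None, None
        for edge in _edges(adj):
            cand = _copy(adj)
            _attach_leaf(cand, leaf, edge, nxt)
            sc = _score_adj(cand, enc)
            if best is None or sc < best:
                best, best_adj = sc, cand
        adj = best_adj
        nxt += 1
    return adj


def tbr_heuristic_search(matrix: CharacterMatrix, n_random_starts: int = 10,
                         seed: int = 0, *, keep: int = 1000,
                         plateau_cap: int = 40) -> SearchResult:
    """Random-addition starts with TBR swapping to a local optimum.

    Deterministic for a given seed.  From each start the swapper descends
    until no TBR neighbor improves, then walks the plateau of equal-score
    neighbors (up to ``plateau_cap`` trees per start, which bounds the work
    on very flat landscapes).  Equally parsimonious trees are pooled across
    starts, deduplicated by their split sets, up to ``keep``.
    """
    n = len(matrix.taxa)
    enc = _Encoded(matrix)
    if n <= 3:
        return branch_and_bound_search(matrix)
    rng = np.random.default_rng(seed)
    best_score: int | None = None
    pool: dict[frozenset, dict[int, list[int]]] = {}

    for _start in range(n_random_starts):
        order = list(rng.permutation(n))
        adj = _greedy_addition(enc, order)
        score = _score_adj(adj, enc)
        frontier = [adj]
        seen = {_splits_sig(adj, n)}
        visited = 0
        while frontier:
            current = frontier.pop()
            visited += 1
            improved = False
            for nb in _tbr_neighbors(current, n):
                sc = _score_adj(nb, enc)
                if sc < score:
                    score, frontier, seen = sc, [nb], {_splits_sig(nb, n)}
                    visited = 0
                    improved = True
                    break
                if sc == score and visited <= plateau_cap and len(seen) < keep:
                    sig = _splits_sig(nb, n)
                    if sig not in seen:
                        seen.add(sig)
                        frontier.append(nb)
            if improved:
                continue
            sig = _splits_sig(current, n)
            if best_score is None or score < best_score:
                best_score = score
                pool.clear()
            if score == best_score and len(pool) < keep:
                pool.setdefault(sig, current)
            if visited > plateau_cap:
                break

    trees = [_adj_to_tree(a, enc, best_score) for a in pool.values()]
    trees.sort(key=lambda t: t.newick())
    return SearchResult(trees, best_score)


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapOptions:
    n_random_starts: int = 2
    exact_below: int = 0      # use branch-and-bound when n_taxa <= this


def bootstrap_support(matrix: CharacterMatrix, replicates: int = 1000,
                      seed: int = 0,
                      search: BootstrapOptions | None = None) -> dict[frozenset, float]:
    """Character-bootstrap clade frequencies (percent).

    Characters are resampled with replacement; each replicate is searched
    and contributes one split-vote, fractional across its equally best
    trees.  Per-replicate seeds derive from ``seed`` by counter, so runs are
    reproducible and replicates independent.  Only nontrivial splits are
    tallied (the all-taxon clade is never reported).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if search is None:
        search = BootstrapOptions()
    votes: dict[frozenset, float] = {}
    nchar = matrix.n_characters
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, nchar, size=nchar)
        boot = matrix.resample(list(idx))
        if len(matrix.taxa) <= search.exact_below:
            res = branch_and_bound_search(boot)
        else:
            res = tbr_heuristic_search(
                boot, n_random_starts=search.n_random_starts,
                seed=int(rng.integers(0, 2**31)))
        w = 1.0 / len(res.trees)
        for t in res.trees:
            for split in t.splits():
                votes[split] = votes.get(split, 0.0) + w
    return {s: 100.0 * v / replicates for s, v in votes.items()}
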