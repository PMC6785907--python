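"""Phylogenetic tree container: Newick IO, splits, consensus, RF distance.

Trees are stored as an arborescence of :class:`Node`; unrooted trees keep a
basal multifurcation and ``rooted=False``.  Newick parsing is delegated to
dendropy; everything downstream (splits, consensus, Robinson-Foulds) works on
bipartition sets, the natural currency of unrooted tree comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = ["Node", "PhyloTree", "strict_consensus", "rf_distance"]


@dataclass
class Node:
    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.walk() if n.is_leaf]

    def copy(self) -> "Node":
        return Node(self.label, [c.copy() for c in self.children],
                    self.length, self.support)


class PhyloTree:
    """A tree over taxon labels, rooted or unrooted.

    Unrooted trees with n >= 3 leaves never carry degree-2 internal vertices;
    rooted trees have a (possibly bifurcating) root.  ``length`` holds a
    parsimony score when the tree came out of a search; per-clade ``support``
    values live on internal nodes (percent).
    """

    def __init__(self, root: Node, rooted: bool = False,
                 length: float | None = None):
        self.root = root
        self.rooted = rooted
        self.length = length
        labels = root.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dup}")
        self.leaves: tuple[str, ...] = tuple(sorted(labels))
        if not rooted and len(self.leaves) >= 3:
            self._suppress_unifurcations()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
        def conv(dn) -> Node:
            n = Node(
                label=dn.taxon.label if dn.taxon is not None else dn.label,
                length=dn.edge.length,
            )
            if n.label is not None and not dn.is_leaf():
                try:
                    n.support = float(n.label)
                    n.label = None
                except ValueError:
                    pass
            n.children = [conv(c) for c in dn.child_nodes()]
            return n
        root = conv(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    @classmethod
    def from_nested(cls, spec, rooted: bool = False) -> "PhyloTree":
        """Build from nested tuples/lists of labels, e.g. ("A", ("B", "C"))."""
        def conv(s) -> Node:
            if isinstance(s, str):
                return Node(label=s)
            return Node(children=[conv(x) for x in s])
        return cls(conv(spec), rooted=rooted)

    # -- output ------------------------------------------------------------

    def newick(self, *, include_support: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                lab = n.label
                if any(c in lab for c in " (),:;"):
                    lab = "'" + lab.replace("'", "''") + "'"
                s = lab
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if include_support and n.support is not None:
                    s += f"{n.support:g}"
            if n.length is not None:
                s += f":{n.length:g}"
            return s
        return fmt(self.root) + ";"

    def __repr__(self) -> str:
        return f"PhyloTree({self.newick()!r}, rooted={self.rooted})"

    # -- structure ---------------------------------------------------------

    def _suppress_unifurcations(self) -> None:
        def fix(n: Node) -> Node:
            while len(n.children) == 1:
                child = n.children[0]
                child.length = (n.length or 0) + (child.length or 0) or None
                n = child
            n.children = [fix(c) for c in n.children]
            return n
        self.root = fix(self.root)

    def splits(self, *, nontrivial_only: bool = True) -> set[frozenset]:
        """Bipartitions as frozensets of the leaf subset NOT containing the
        alphabetically first taxon (a rooting-free normal form)."""
        anchor = self.leaves[0]
        full = set(self.leaves)
        out: set[frozenset] = set()

        def below(n: Node) -> set[str]:
            if n.is_leaf:
                return {n.label}
            s: set[str] = set()
            for c in n.children:
                cs = below(c)
                s |= cs
            if n is not self.root:
                side = s if anchor not in s else full - s
                if not nontrivial_only or 1 < len(side) < len(full) - 1:
                    out.add(frozenset(side))
            return s

        below(self.root)
        return out

    def clades(self) -> set[frozenset]:
        """Leaf sets of all internal nodes (rooted trees)."""
        if not self.rooted:
            raise ValueError("clades are defined on rooted trees; use splits()")
        out = set()
        def below(n: Node) -> set[str]:
            if n.is_leaf:
                return {n.label}
            s: set[str] = set()
            for c in n.children:
                s |= below(c)
            out.add(frozenset(s))
            return s
        below(self.root)
        return out

    def is_monophyletic(self, group: Iterable[str]) -> bool:
        g = frozenset(group)
        if not g <= set(self.leaves):
            raise ValueError("group not a subset of the leaf set")
        if self.rooted:
            return g in self.clades() or len(g) == 1
        if len(g) == 1 or len(g) >= len(self.leaves) - 1:
            return True
        anchor = self.leaves[0]
        side = g if anchor not in g else frozenset(set(self.leaves) - g)
        return side in self.splits(nontrivial_only=False)

    def annotate_support(self, support: dict[frozenset, float]) -> None:
        """Attach clade support percentages (keys = normalized splits)."""
        anchor = self.leaves[0]
        full = set(self.leaves)
        def below(n: Node) -> set[str]:
            if n.is_leaf:
                return {n.label}
            s: set[str] = set()
            for c in n.children:
                s |= below(c)
            side = frozenset(s if anchor not in s else full - s)
            if side in support:
                n.support = support[side]
            return s
        below(self.root)


def _tree_from_splits(leaves: Sequence[str], splits: Iterable[frozenset]) -> PhyloTree:
    """Build the (possibly multifurcating) unrooted tree exhibiting exactly
    the given compatible normalized splits."""
    leaves = sorted(leaves)
    anchor = leaves[0]
    # treat as rooted-at-anchor clades; nest by containment
    clades = sorted({frozenset(s) for s in splits}, key=len, reverse=True)
    root = Node(children=[Node(label=anchor)])
    holder: dict[frozenset, Node] = {frozenset(leaves): root}

    def place(target: frozenset, node_sets: list[frozenset]) -> frozenset:
        best = frozenset(leaves)
        for s in node_sets:
            if target < s and len(s) < len(best):
                best = s
        return best

    placed: list[frozenset] = [frozenset(leaves)]
    for cl in clades:
        parent = holder[place(cl, placed)]
        node = Node()
        parent.children.append(node)
        holder[cl] = node
        placed.append(cl)
    for leaf in leaves[1:]:
        parent = holder[place(frozenset([leaf]), placed)]
        parent.children.append(Node(label=leaf))
    return PhyloTree(root, rooted=False)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Tree containing exactly the splits present in every input tree."""
    if not trees:
        raise ValueError("no trees")
    leafsets = {t.leaves for t in trees}
    if len(leafsets) != 1:
        raise ValueError(f"mismatched leaf sets: {sorted(leafsets, key=len)}")
    common = set.intersection(*(set(t.splits()) for t in trees))
    return _tree_from_splits(trees[0].leaves, common)


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds: symmetric difference of nontrivial bipartitions."""
    if a.leaves != b.leaves:
        raise ValueError(f"leaf sets differ: {set(a.leaves) ^ set(b.leaves)}")
    return len(a.splits() ^ b.splits())
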