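"""Outgroup rooting, MPR state sets, and per-node chromosomal signatures.

Ancestral states for unordered characters are summarized as MPR sets: the
states a node takes in at least one most-parsimonious reconstruction,
computed by a two-pass 0/1-cost dynamic program (subtree costs down,
outside costs up), which handles polytomies and missing data exactly.
Branch changes are reported with an ``unambiguous`` flag -- true when every
most-parsimonious reconstruction changes state on that branch -- rather
than being resolved by ACCTRAN/DELTRAN, so the full MPR envelope is
visible.

Signatures are rendered in the field's notation: association gains appear
as slash-joined probe chains ordered along the carrier chromosome (e.g.
"HME 20/(13,22)/4", "19/14/19"), with sub-block letters for the probes the
study letters (6, 7, 8) and two-segment signals shown on both flanks
("(9,10)/7b/(9,10)").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .coding import CharacterMatrix
from .painting import HomologyTable, PROBES
from .trees import Node, PhyloTree

__all__ = [
    "NodeSignature", "root_with_outgroup", "mpr_state_sets",
    "branch_synapomorphies", "render_association",
]

_INF = 10 ** 9


@dataclass
class NodeSignature:
    """Character changes forced (or allowed) on the branch under one node."""

    node: frozenset
    changes: list[tuple[str, str, str, bool]] = field(default_factory=list)
    rendered: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rooting

def root_with_outgroup(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root on the branch separating ``outgroup`` from the remaining taxa.

    The outgroup must be a proper, monophyletic subset (i.e. one side of a
    branch of the unrooted tree); otherwise the offending split is reported.
    """
    og = frozenset(outgroup)
    leaves = set(tree.leaves)
    if not og or not og < leaves:
        raise ValueError("outgroup must be a nonempty proper subset of the taxa")
    if len(og) == len(leaves):
        raise ValueError("outgroup cannot contain every taxon")

    # adjacency over nodes
    nodes: list[Node] = list(tree.root.walk())
    idx = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            adj[idx[id(n)]].append(idx[id(c)])
            adj[idx[id(c)]].append(idx[id(n)])
    labels = {i: n.label for i, n in enumerate(nodes)}

    # find the edge whose side equals the outgroup
    target = None
    for u in adj:
        for v in adj[u]:
            side = _side_leaves(adj, labels, v, u)
            if side == og:
                target = (u, v)
                break
        if target:
            break
    if target is None:
        sides = sorted((
            _side_leaves(adj, labels, v, u) for u in adj for v in adj[u]),
            key=lambda s: len(s & og), reverse=True)
        best = sides[0] if sides else frozenset()
        raise ValueError(
            f"outgroup {sorted(og)} is not monophyletic; closest split side "
            f"is {sorted(best)}")

    u, v = target  # v-side == outgroup

    def build(node: int, parent: int) -> Node:
        kids = [build(x, node) for x in adj[node] if x != parent]
        return Node(label=labels[node], children=kids)

    root = Node(children=[build(v, u), build(u, v)])
    return PhyloTree(root, rooted=True, length=tree.length)


def _side_leaves(adj, labels, start: int, banned: int) -> frozenset:
    out, stack, seen = [], [start], {start, banned}
    while stack:
        x = stack.pop()
        if labels[x] is not None and not [y for y in adj[x] if y not in seen]:
            pass
        if labels[x] is not None:
            out.append(labels[x])
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return frozenset(out)


# ---------------------------------------------------------------------------
# MPR machinery (0/1 Sankoff)

def _column(matrix: CharacterMatrix, j: int):
    return matrix.column(j), len(matrix.characters[j].state_labels)


def _down_costs(node: Node, column, nstates: int, table: dict) -> list[int]:
    if node.is_leaf:
        s = column.get(node.label)
        costs = [0 if (s is None or s == k) else _INF for k in range(nstates)]
    else:
        kid_costs = [_down_costs(c, column, nstates, table) for c in node.children]
        costs = []
        for k in range(nstates):
            tot = 0
            for cc in kid_costs:
                m = min(cc)
                tot += min(cc[k], m + 1)
            costs.append(tot)
    table[id(node)] = costs
    return costs


def _up_costs(tree: PhyloTree, column, nstates: int, down: dict) -> dict:
    """outside-subtree cost per state, for every node."""
    up = {id(tree.root): [0] * nstates}

    def visit(node: Node) -> None:
        base = up[id(node)]
        kid_costs = [down[id(c)] for c in node.children]
        for i, child in enumerate(node.children):
            a = []
            for s in range(nstates):
                tot = base[s]
                for k, cc in enumerate(kid_costs):
                    if k != i:
                        tot += min(cc[s], min(cc) + 1)
                a.append(tot)
            mina = min(a)
            up[id(child)] = [min(a[t], mina + 1) for t in range(nstates)]
            up.setdefault("_A", {})[id(child)] = a  # parent-side cost, pre-edge
            visit(child)

    visit(tree.root)
    return up


def mpr_state_sets(tree: PhyloTree, matrix: CharacterMatrix
                   ) -> dict[frozenset, dict[int, frozenset]]:
    """For every node (keyed by its leaf set), per character, the set of
    states occurring in at least one most-parsimonious assignment."""
    if not tree.rooted:
        raise ValueError("mpr_state_sets expects a rooted tree")
    _check(tree, matrix)
    out: dict[frozenset, dict[int, frozenset]] = {}
    for j in range(matrix.n_characters):
        column, nstates = _column(matrix, j)
        down: dict = {}
        _down_costs(tree.root, column, nstates, down)
        up = _up_costs(tree, column, nstates, down)
        total = min(down[id(tree.root)])
        for node in tree.root.walk():
            d = down[id(node)]
            u = up[id(node)]
            key = frozenset(n.label for n in node.walk() if n.is_leaf)
            states = frozenset(
                s for s in range(nstates) if d[s] + u[s] == total)
            out.setdefault(key, {})[j] = states
    return out


def _check(tree: PhyloTree, matrix: CharacterMatrix) -> None:
    tl, ml = set(tree.leaves), set(matrix.taxa)
    if tl != ml:
        raise ValueError(f"tree/matrix taxa differ: {sorted(tl ^ ml)}")


def branch_synapomorphies(tree: PhyloTree, matrix: CharacterMatrix,
                          table: HomologyTable | None = None,
                          *, include_ambiguous: bool = True
                          ) -> list[NodeSignature]:
    """Per-node character changes on the subtending branch.

    A change is unambiguous when no most-parsimonious reconstruction keeps
    the branch constant; ambiguous changes (made on this branch in some but
    not all MPRs) are flagged rather than resolved.  When ``table`` is
    given, association-character gains are rendered as chromosomal
    signature strings via :func:`render_association`.
    """
    if not tree.rooted:
        raise ValueError("branch_synapomorphies expects a rooted tree")
    _check(tree, matrix)
    sigs: dict[frozenset, NodeSignature] = {}

    for j in range(matrix.n_characters):
        column, nstates = _column(matrix, j)
        down: dict = {}
        _down_costs(tree.root, column, nstates, down)
        up = _up_costs(tree, column, nstates, down)
        total = min(down[id(tree.root)])
        A = up.get("_A", {})
        cdef = matrix.characters[j]

        for node in tree.root.walk():
            if node is tree.root or id(node) not in A:
                continue
            a = A[id(node)]
            d = down[id(node)]
            t_same = min(a[s] + d[s] for s in range(nstates))
            pairs = [(s, t) for s in range(nstates) for t in range(nstates)
                     if s != t and a[s] + 1 + d[t] == total]
            if not pairs:
                continue
            forced = t_same > total
            if not forced and not include_ambiguous:
                continue
            froms = sorted({s for s, _ in pairs})
            tos = sorted({t for _, t in pairs})
            key = frozenset(n.label for n in node.walk() if n.is_leaf)
            sig = sigs.setdefault(key, NodeSignature(node=key))
            sig.changes.append((
                cdef.label,
                "/".join(cdef.state_labels[s] for s in froms),
                "/".join(cdef.state_labels[t] for t in tos),
                forced,
            ))

    if table is not None:
        for sig in sigs.values():
            sig.rendered = _render_signature(sig, table)
    return sorted(sigs.values(), key=lambda s: (-len(s.node), sorted(s.node)))


# ---------------------------------------------------------------------------
# rendering

_LETTERED = {"6", "7", "8"}
_REGION_RANK = {"prox": 2, "int": 1, "dist": 0}


def _position_key(loc) -> tuple:
    # order along the chromosome: p telomere -> centromere -> q telomere
    if loc.arm == "p":
        return (0, _REGION_RANK.get(loc.regions[0], 1) if loc.regions else 1)
    if loc.arm == "q":
        return (1, 5 - _REGION_RANK.get(loc.regions[0], 1) if loc.regions else 4)
    return (1, 3)


def _subblock_letter(table: HomologyTable, taxon: str, probe: str, chrom: str) -> str:
    """a/b letter for lettered probes, from the sub-block registry."""
    if probe not in _LETTERED:
        return ""
    try:
        from .rearrange import load_segment_registry
        reg = load_segment_registry()
    except Exception:
        return ""
    for seg in reg.segments:
        if reg.probe[seg] == probe and reg.placement[seg].get(taxon) == chrom:
            suffix = seg[len(probe):]
            return suffix if suffix in ("a", "b") else ""
    return ""


def render_association(table: HomologyTable, taxon: str, chromosome: str) -> str:
    """Signature string for one chromosome of one taxon: probes along the
    chromosome joined by '/', two-segment signals shown on both flanks."""
    entries = []
    for p in table.probes:
        for loc in table.entries[(taxon, p)]:
            if loc.chromosome == chromosome:
                entries.append((loc, p))
    entries.sort(key=lambda e: _position_key(e[0]))
    tokens: list[str] = []
    for loc, p in entries:
        name = p + _subblock_letter(table, taxon, p, chromosome)
        if loc.two_segment and len(entries) > 1:
            tokens.insert(0, name)
            tokens.append(name)
        else:
            tokens.append(name)
    return "/".join(tokens)


def _render_signature(sig: NodeSignature, table: HomologyTable) -> list[str]:
    """Render association gains at a node as merged signature chains."""
    gained_pairs = []
    other = []
    for label, frm, to, forced in sig.changes:
        if label.startswith("association HME ") and to == "present":
            pair = tuple(label[len("association HME "):].split("/", 1))
            gained_pairs.append(pair)
        elif label.startswith("association HME ") and to == "absent":
            other.append(f"loss of HME {label[len('association HME '):]}")
        else:
            other.append(f"{label}: {frm} -> {to}")
    if not gained_pairs:
        return other

    # merge gained pairs into components, then find a carrier chromosome in
    # a clade member exhibiting the whole component
    import networkx as nx
    G = nx.Graph(gained_pairs)
    rendered = []
    for comp in nx.connected_components(G):
        carrier = None
        for taxon in sorted(sig.node):
            contents: dict[str, set] = {}
            for p in table.probes:
                for loc in table.entries[(taxon, p)]:
                    contents.setdefault(loc.chromosome, set()).add(p)
            for chrom, ps in sorted(contents.items()):
                if comp <= ps:
                    carrier = (taxon, chrom)
                    break
            if carrier:
                break
        if carrier:
            rendered.append("HME " + render_association(table, *carrier))
        else:
            rendered.append("HME " + "/".join(sorted(comp)))
    return rendered + other
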