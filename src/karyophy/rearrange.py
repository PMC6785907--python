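"""Chromosomal rearrangement inference from painting homology maps.

Karyotypes are compared as partitions of a fixed universe of syntenic
sub-block segments (the registry shipped with the fixture): each chromosome
is the set of segments it carries.  Fusions and fissions are partition
merges and splits; the minimal number converting one partition into another
is ``|P| + |Q| - 2c`` with ``c`` the number of connected components of the
group-intersection graph (a metric on partitions).

The tree-based tally reconstructs ancestral partitions on a rooted ingroup
topology by Fitch reconstruction of each pairwise segment adjacency
(co-residence on one chromosome), repaired to proper partitions by
transitive closure, then decomposes every branch's difference into
elementary events:

* a single segment excised from a multi-segment chromosome and inserted
  into a surviving multi-segment chromosome is one *translocation*;
* every other change is a *fusion* (two parts join) or *fission* (a
  chromosome splits);
* identical events (same segments, same parts) arising on several branches
  are counted once -- the tally counts distinct chromosome-membership
  changes, not branch occurrences.

Morphology-only differences between chromosomes of identical segment
content are classified from the karyotype descriptors: explained by a
constitutive-heterochromatin (CH) arm on one side -> CH amplification or
deletion of the blocks involved; otherwise -> pericentric inversion.  The
X chromosome is excluded from fusion/fission and tracked separately for CH.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .painting import HomologyTable, PaintingError, PROBES
from .trees import Node, PhyloTree

__all__ = [
    "SegmentRegistry", "BlockPartition", "RearrangementEvent", "EventTally",
    "load_segment_registry", "chromosome_partition", "partition_edit_distance",
    "tree_event_tally", "neacomys_ingroup_tree", "NEACOMYS_KARYOTYPES",
]

#: The seven painted karyotypes of the six ingroup species.
NEACOMYS_KARYOTYPES: tuple[str, ...] = (
    "NSP-A", "NSP-B", "NSP-C", "NSP-D", "NPA", "NSP-E", "NAM")


def neacomys_ingroup_tree() -> PhyloTree:
    """The published ingroup topology: NAM sister to the rest, a polytomy of
    NSP-B, NSP-E and the (NPA,(NSP-A,(NSP-C,NSP-D))) core."""
    return PhyloTree.from_nested(
        ("NAM", ("NSP-B", "NSP-E", ("NPA", ("NSP-A", ("NSP-C", "NSP-D"))))),
        rooted=True)


def sigmodontinae_reference_tree() -> PhyloTree:
    """The study's chromosomal topology over all 15 karyotypes, rooted
    between the Akodontini (TNI, NLA, AMO, ASP) and the Oryzomyini.

    Within Akodontini: TNI sister to the rest, then NLA, then the Akodon
    pair.  Within Oryzomyini the Oecomys pair is sister to the Neacomys
    clade of :func:`neacomys_ingroup_tree`.
    """
    return PhyloTree.from_nested(
        (("TNI", ("NLA", ("AMO", "ASP"))),
         ("CLA", ("HME", (("OCA-PA", "OCA-RJ"),
          ("NAM", ("NSP-B", "NSP-E",
                   ("NPA", ("NSP-A", ("NSP-C", "NSP-D"))))))))),
        rooted=True)


# ---------------------------------------------------------------------------
# registry

@dataclass
class SegmentRegistry:
    """Versioned sub-block registry: segment -> probe, and placement
    (segment -> taxon -> chromosome).  Granularity determines event counts,
    so the registry is fixture data, not derived at run time."""

    segments: tuple[str, ...]
    probe: dict[str, str]
    placement: dict[str, dict[str, str]]
    taxa: tuple[str, ...]
    version: str = "1"

    def partition(self, taxon: str, *, include_x: bool = False) -> "BlockPartition":
        groups: dict[str, set[str]] = {}
        for seg in self.segments:
            if not include_x and self.probe[seg] == "X":
                continue
            chrom = self.placement[seg].get(taxon)
            if chrom is None:
                raise KeyError(f"registry has no placement for {seg} in {taxon}")
            groups.setdefault(chrom, set()).add(seg)
        return BlockPartition(
            taxon=taxon,
            groups=tuple(frozenset(g) for _, g in sorted(groups.items())),
            chromosomes=tuple(sorted(groups)),
        )


def load_segment_registry(path: str | Path | None = None) -> SegmentRegistry:
    if path is None:
        path = Path(str(resources.files("karyophy") / "fixtures" / "segments.tsv"))
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    taxa = tuple(header[2:])
    segments, probe, placement = [], {}, {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        seg = cells[0]
        segments.append(seg)
        probe[seg] = cells[1]
        placement[seg] = dict(zip(taxa, cells[2:]))
    return SegmentRegistry(tuple(segments), probe, placement, taxa)


# ---------------------------------------------------------------------------
# partitions

@dataclass
class BlockPartition:
    """One taxon's chromosomes as disjoint groups of registry segments."""

    taxon: str
    groups: tuple[frozenset, ...]
    chromosomes: tuple[str, ...] = ()

    def __post_init__(self):
        all_segs = [s for g in self.groups for s in g]
        if len(all_segs) != len(set(all_segs)):
            raise ValueError(f"{self.taxon}: segment in more than one group")
        if any(not g for g in self.groups):
            raise ValueError(f"{self.taxon}: empty group")

    @property
    def universe(self) -> frozenset:
        return frozenset(s for g in self.groups for s in g)

    def __len__(self) -> int:
        return len(self.groups)


def chromosome_partition(table: HomologyTable, taxon: str,
                         registry: SegmentRegistry | None = None,
                         *, include_x: bool = True) -> BlockPartition:
    """The taxon's chromosomes as segment groups, validated against the
    homology table (every registry placement must be a painted chromosome of
    that probe, and vice versa)."""
    if registry is None:
        registry = load_segment_registry()
    table._check_taxon(taxon)
    for p in table.probes:
        painted = {loc.chromosome for loc in table.entries[(taxon, p)]}
        placed = {registry.placement[s].get(taxon)
                  for s in registry.segments if registry.probe[s] == p}
        placed.discard(None)
        if placed and painted != placed:
            missing = painted ^ placed
            raise PaintingError(
                f"registry/table mismatch for {taxon} probe {p}: "
                f"chromosomes {sorted(missing)} differ")
    return registry.partition(taxon, include_x=include_x)


def partition_edit_distance(p: BlockPartition, q: BlockPartition
                            ) -> tuple[int, int]:
    """Minimal (fissions, fusions) converting ``p`` into ``q``.

    Within each connected component of the group-intersection graph, the
    cheapest route merges the ``np`` source groups and splits into the
    ``nq`` target groups, giving ``np - 1`` fusions and ``nq - 1`` fissions;
    the total ``|P| + |Q| - 2c`` is a metric.
    """
    if p.universe != q.universe:
        raise ValueError(
            f"segment universes differ: {sorted(p.universe ^ q.universe)}")
    comps = _intersection_components(p.groups, q.groups)
    fissions = sum(len(qs) - 1 for _, qs in comps)
    fusions = sum(len(ps) - 1 for ps, _ in comps)
    return fissions, fusions


def _intersection_components(pg: Sequence[frozenset], qg: Sequence[frozenset]):
    G = nx.Graph()
    G.add_nodes_from(("p", i) for i in range(len(pg)))
    G.add_nodes_from(("q", j) for j in range(len(qg)))
    for i, g in enumerate(pg):
        for j, h in enumerate(qg):
            if g & h:
                G.add_edge(("p", i), ("q", j))
    out = []
    for comp in nx.connected_components(G):
        ps = [pg[i] for side, i in comp if side == "p"]
        qs = [qg[j] for side, j in comp if side == "q"]
        out.append((ps, qs))
    return out


# ---------------------------------------------------------------------------
# tree-based tally

@dataclass(frozen=True)
class RearrangementEvent:
    kind: str                     # fusion | fission | translocation
    parts: tuple[frozenset, ...]  # for transloc: (segment, source, dest core)
    result: frozenset
    branches: tuple[frozenset, ...] = ()

    def describe(self, registry: SegmentRegistry | None = None) -> str:
        def nm(fs):
            return "{" + ",".join(sorted(fs)) + "}"
        if self.kind == "translocation":
            seg, src, dst = self.parts
            return (f"translocation of {nm(seg)} from {nm(src)} into {nm(dst)}")
        arrow = " + ".join(nm(x) for x in self.parts)
        if self.kind == "fusion":
            return f"fusion {arrow} -> {nm(self.result)}"
        return f"fission {nm(self.result)} -> {arrow}"


@dataclass
class EventTally:
    fusion_fission: int
    translocation: int
    inverted_blocks: set[str]
    ch_changed_blocks: set[str]
    x_ch_changed: bool
    events: list[RearrangementEvent] = field(default_factory=list)
    per_branch_moves: dict[frozenset, int] = field(default_factory=dict)

    @property
    def total_moves(self) -> int:
        return sum(self.per_branch_moves.values())


def _fitch_binary_final(tree: PhyloTree, states: dict[str, int]) -> dict[int, int]:
    """Deterministic Fitch final states (ties resolve to the parent state;
    the root resolves to absent) keyed by id(node)."""
    down: dict[int, frozenset] = {}

    def dp(node: Node) -> frozenset:
        if node.is_leaf:
            s = frozenset([states[node.label]])
        else:
            sets = [dp(c) for c in node.children]
            inter = frozenset.intersection(*sets)
            s = inter if inter else frozenset.union(*sets)
        down[id(node)] = s
        return s

    dp(tree.root)
    final: dict[int, int] = {}

    def up(node: Node, parent_state: int | None) -> None:
        s = down[id(node)]
        if parent_state is not None and parent_state in s:
            st = parent_state
        else:
            st = 0 if 0 in s else 1
        final[id(node)] = st
        for c in node.children:
            up(c, st)

    up(tree.root, None)
    return final


def _ancestral_partitions(tree: PhyloTree, tips: dict[str, BlockPartition]
                          ) -> dict[int, tuple[frozenset, ...]]:
    universe = sorted(next(iter(tips.values())).universe)
    seg_group = {t: {s: g for g in p.groups for s in g} for t, p in tips.items()}
    finals: dict[tuple[str, str], dict[int, int]] = {}
    for a, b in itertools.combinations(universe, 2):
        states = {t: int(seg_group[t][a] is seg_group[t].get(b))
                  for t in tips}
        if any(states.values()):
            finals[(a, b)] = _fitch_binary_final(tree, states)
    parts: dict[int, tuple[frozenset, ...]] = {}
    for node in tree.root.walk():
        if node.is_leaf:
            continue
        G = nx.Graph()
        G.add_nodes_from(universe)
        for pair, fin in finals.items():
            if fin[id(node)]:
                G.add_edge(*pair)
        parts[id(node)] = tuple(frozenset(c)
                                for c in nx.connected_components(G))
    return parts


def _branch_events(parent: Sequence[frozenset], child: Sequence[frozenset]
                   ) -> tuple[list[RearrangementEvent], int]:
    """Elementary events on one branch, and the raw move count."""
    events: list[RearrangementEvent] = []
    moves = 0
    for ps, qs in _intersection_components(parent, child):
        if len(ps) == 1 and len(qs) == 1:
            continue
        moves += len(ps) + len(qs) - 2
        atoms = [g & h for g in ps for h in qs if g & h]

        # translocations: a lone segment leaving a multi-segment chromosome
        # and landing in a child chromosome that keeps another multi-segment
        # parent chromosome intact
        translocated: set[str] = set()
        for h in qs:
            h_atoms = [a for a in atoms if a <= h]
            cores = [a for a in h_atoms if len(a) >= 2 and a in ps]
            if not cores:
                continue
            for a in h_atoms:
                if len(a) == 1:
                    (seg,) = a
                    src = next((g for g in ps if seg in g), None)
                    if src is not None and len(src) >= 2:
                        events.append(RearrangementEvent(
                            kind="translocation",
                            parts=(frozenset([seg]), src, cores[0]),
                            result=h))
                        translocated.add(seg)

        # k-way splits/merges decompose into binary peels off the largest
        # atom, so identical changes on different branches share a signature
        def peels(group, group_atoms):
            kept = [a - translocated for a in group_atoms]
            kept = sorted((a for a in kept if a),
                          key=lambda a: (-len(a), sorted(a)))
            return kept

        for g in ps:
            kept = peels(g, [a for a in atoms if a <= g])
            src = frozenset(g) - translocated
            for a in kept[1:]:
                events.append(RearrangementEvent(
                    kind="fission", parts=(a,), result=src))
        for h in qs:
            kept = peels(h, [a for a in atoms if a <= h])
            dst = frozenset(h) - translocated
            for a in kept[1:]:
                events.append(RearrangementEvent(
                    kind="fusion", parts=(a,), result=dst))
    return events, moves


def tree_event_tally(table: HomologyTable,
                     taxa: Sequence[str] = NEACOMYS_KARYOTYPES,
                     tree: PhyloTree | None = None,
                     registry: SegmentRegistry | None = None) -> EventTally:
    """Parsimonious rearrangement tally for ``taxa`` on a rooted topology.

    Fusion/fission and translocation counts are numbers of *distinct*
    events across the whole tree; ``per_branch_moves`` keeps the raw
    per-branch split/merge counts for bound checks.  Inversion and CH
    classifications compare same-content chromosomes between taxa using the
    karyotype descriptors (unknown morphologies are skipped).
    """
    if registry is None:
        registry = load_segment_registry()
    if tree is None:
        tree = neacomys_ingroup_tree()
    if set(tree.leaves) != set(taxa):
        raise ValueError(
            f"tree leaves {sorted(tree.leaves)} != taxa {sorted(taxa)}")
    if not tree.rooted:
        raise ValueError("tree_event_tally expects a rooted tree")
    tips = {t: chromosome_partition(table, t, registry, include_x=False)
            for t in taxa}
    anc = _ancestral_partitions(tree, tips)

    distinct: dict[tuple, RearrangementEvent] = {}
    per_branch: dict[frozenset, int] = {}

    def walk(node: Node, parent: Node | None) -> None:
        if parent is not None:
            pgroups = anc[id(parent)]
            cgroups = (tips[node.label].groups if node.is_leaf
                       else anc[id(node)])
            evs, moves = _branch_events(pgroups, cgroups)
            clade = frozenset(n.label for n in node.walk() if n.is_leaf)
            per_branch[clade] = moves
            for ev in evs:
                key = (ev.kind, ev.parts, ev.result)
                if key in distinct:
                    old = distinct[key]
                    distinct[key] = RearrangementEvent(
                        ev.kind, ev.parts, ev.result,
                        branches=old.branches + (clade,))
                else:
                    distinct[key] = RearrangementEvent(
                        ev.kind, ev.parts, ev.result, branches=(clade,))
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    events = list(distinct.values())
    n_tl = sum(1 for e in events if e.kind == "translocation")
    n_ff = len(events) - n_tl

    inverted, ch_changed, x_changed = _morphology_events(table, taxa, registry)
    return EventTally(
        fusion_fission=n_ff, translocation=n_tl,
        inverted_blocks=inverted, ch_changed_blocks=ch_changed,
        x_ch_changed=x_changed, events=events, per_branch_moves=per_branch)


def _morphology_events(table: HomologyTable, taxa: Sequence[str],
                       registry: SegmentRegistry
                       ) -> tuple[set[str], set[str], bool]:
    """Same-content, different-morphology chromosome pairs, classified as CH
    (one side carries a CH arm there) or pericentric inversion."""
    biarmed = {"metacentric", "submetacentric"}
    info = {}
    for t in taxa:
        d = table.descriptors.get(t)
        part = registry.partition(t, include_x=False)
        seg_by_chrom: dict[str, frozenset] = {}
        for g, chrom in zip(part.groups, part.chromosomes):
            seg_by_chrom[chrom] = g
        info[t] = (d, seg_by_chrom)

    inverted: set[str] = set()
    ch_changed: set[str] = set()
    for ta, tb in itertools.combinations(taxa, 2):
        da, ga = info[ta]
        db, gb = info[tb]
        if da is None or db is None:
            continue
        for ca, segs in ga.items():
            cb = next((c for c, s in gb.items() if s == segs), None)
            if cb is None:
                continue
            ma = da.chromosome_morphologies.get(ca)
            mb = db.chromosome_morphologies.get(cb)
            if ma is None or mb is None or ma == mb:
                continue
            if (ma in biarmed) == (mb in biarmed):
                continue  # meta vs submeta: below painting resolution
            ch_a = any(c == ca for c, _ in da.ch_blocks)
            ch_b = any(c == cb for c, _ in db.ch_blocks)
            blocks = {registry.probe[s] for s in segs}
            if ch_a != ch_b:
                ch_changed |= blocks
            else:
                inverted |= blocks

    x_states = set()
    for t in taxa:
        d = table.descriptors.get(t)
        if d is not None:
            x_states.add(any(c == "X" for c, _ in d.ch_blocks))
    x_changed = len(x_states) > 1
    return inverted, ch_changed, x_changed


def write_event_report(tally: EventTally, path: str | Path) -> None:
    """TSV event report: one row per distinct event with its branches."""
    with open(path, "w") as fh:
        fh.write("kind\tdescription\tbranches\n")
        for ev in sorted(tally.events, key=lambda e: (e.kind, sorted(e.result))):
            brs = "; ".join(",".join(sorted(b)) for b in ev.branches)
            fh.write(f"{ev.kind}\t{ev.describe()}\t{brs}\n")
        fh.write(f"#fusion_fission\t{tally.fusion_fission}\n")
        fh.write(f"#translocation\t{tally.translocation}\n")
        fh.write(f"#inverted_blocks\t{','.join(sorted(tally.inverted_blocks))}\n")
        fh.write(f"#ch_changed_blocks\t{','.join(sorted(tally.ch_changed_blocks))}\n")
        fh.write(f"#x_ch_changed\t{tally.x_ch_changed}\n")
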