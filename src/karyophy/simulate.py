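"""Karyotype-evolution simulator for end-to-end recovery testing.

An ancestral karyotype distributes conserved syntenic blocks over
chromosomes; fusion, fission, translocation, pericentric inversion and
constitutive-heterochromatin (CH) gain/loss act along the branches of a
known tree, with per-branch event counts Poisson-distributed at the given
rates.  Tips are emitted in the same homology-table form a painting
experiment produces (probe = ancestral block, signal = its location), with
descriptors and a segment registry, so every pipeline stage -- coding,
search, signatures, event tallies -- can be exercised against a known truth
(the event log replays to the tips exactly).

Default rates follow the qualitative ordering the genus shows
(fusion/fission dominate, then inversion, then translocation and CH); the
exact numbers are package defaults, not measurements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .painting import (HomologyTable, KaryotypeDescriptor, SignalLocus)
from .rearrange import SegmentRegistry
from .trees import Node, PhyloTree

__all__ = [
    "Chromosome", "SimKaryotype", "SimEvent", "EventLog", "DEFAULT_RATES",
    "simulate_ancestor", "evolve_on_tree", "apply_event", "replay",
    "recovery_experiment",
]

#: events per unit branch length; fusion/fission dominate, as in the genus
DEFAULT_RATES: dict[str, float] = {
    "fission": 0.5,
    "fusion": 0.5,
    "inversion": 0.15,
    "translocation": 0.05,
    "ch": 0.05,
}

#: the "at most one event per branch" regime (total 0.25 expected events per
#: unit branch, so multi-event branches are rare) used by recovery studies
LOW_RATES: dict[str, float] = {
    "fission": 0.10,
    "fusion": 0.10,
    "inversion": 0.03,
    "translocation": 0.01,
    "ch": 0.01,
}


@dataclass(frozen=True)
class Chromosome:
    """Ordered block segments with a centromere index and CH arm flags.

    ``centromere`` counts how many segments sit on the p arm (0 = acrocentric
    unless a CH arm provides the second arm).
    """

    segments: tuple[str, ...]
    centromere: int = 0
    ch_p: bool = False
    ch_q: bool = False

    def __post_init__(self):
        if not self.segments:
            raise ValueError("empty chromosome")
        if not (0 <= self.centromere <= len(self.segments)):
            raise ValueError("centromere out of range")

    @property
    def biarmed(self) -> bool:
        return (0 < self.centromere < len(self.segments)) or self.ch_p

    @property
    def morphology(self) -> str:
        return "submetacentric" if self.biarmed else "acrocentric"


@dataclass
class SimKaryotype:
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        segs = [s for c in self.chromosomes for s in c.segments]
        if len(segs) != len(set(segs)):
            raise ValueError("segment appears twice")

    @property
    def segments(self) -> frozenset:
        return frozenset(s for c in self.chromosomes for s in c.segments)

    @property
    def diploid_number(self) -> int:
        return 2 * len(self.chromosomes) + 2   # autosome pairs + XY

    @property
    def fundamental_number(self) -> int:
        return 2 * sum(2 if c.biarmed else 1 for c in self.chromosomes)


@dataclass(frozen=True)
class SimEvent:
    kind: str
    detail: tuple   # kind-specific, sufficient for deterministic replay


@dataclass
class EventLog:
    """Per-branch events, keyed by the clade (leaf set) below the branch."""

    ancestor: SimKaryotype
    branches: dict[frozenset, list[SimEvent]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def count(self, kind: str) -> int:
        return sum(1 for evs in self.branches.values()
                   for e in evs if e.kind == kind)

    @property
    def n_events(self) -> int:
        return sum(len(evs) for evs in self.branches.values())


def simulate_ancestor(n_blocks: int = 26, n_chromosomes: int = 22,
                      seed: int = 0) -> SimKaryotype:
    """Random ancestral karyotype: blocks distributed uniformly over
    chromosomes, each chromosome receiving at least one block."""
    if not (1 <= n_chromosomes <= n_blocks):
        raise ValueError(
            f"need 1 <= n_chromosomes <= n_blocks, got {n_chromosomes} > {n_blocks}")
    rng = np.random.default_rng(seed)
    blocks = [f"B{i + 1:02d}" for i in range(n_blocks)]
    order = list(rng.permutation(blocks))
    # one block each, then the rest uniformly
    homes: dict[int, list[str]] = {i: [order[i]] for i in range(n_chromosomes)}
    for b in order[n_chromosomes:]:
        homes[int(rng.integers(n_chromosomes))].append(b)
    chroms = []
    for i in range(n_chromosomes):
        segs = tuple(homes[i])
        cent = int(rng.integers(0, 2)) and int(rng.integers(0, len(segs) + 1))
        chroms.append(Chromosome(segments=segs, centromere=cent))
    return SimKaryotype(tuple(_sorted_chromosomes(chroms)))


def _sorted_chromosomes(chroms: Iterable[Chromosome]) -> list[Chromosome]:
    return sorted(chroms, key=lambda c: (-len(c.segments), c.segments))


# ---------------------------------------------------------------------------
# event application (pure functions, replayable)

def apply_event(k: SimKaryotype, ev: SimEvent) -> SimKaryotype:
    chroms = list(k.chromosomes)

    def find(segs: tuple) -> int:
        for i, c in enumerate(chroms):
            if c.segments == segs:
                return i
        raise ValueError(f"no chromosome {segs} to apply {ev.kind}")

    if ev.kind == "fission":
        segs, cut = ev.detail
        i = find(segs)
        c = chroms.pop(i)
        left = Chromosome(c.segments[:cut],
                          centromere=min(c.centromere, cut), ch_p=c.ch_p)
        right = Chromosome(c.segments[cut:],
                           centromere=max(0, c.centromere - cut), ch_q=c.ch_q)
        chroms += [left, right]
    elif ev.kind == "fusion":
        segs_a, segs_b = ev.detail
        ia = find(segs_a)
        a = chroms.pop(ia)
        ib = find(segs_b)
        b = chroms.pop(ib)
        chroms.append(Chromosome(a.segments + b.segments,
                                 centromere=len(a.segments),
                                 ch_p=a.ch_p, ch_q=b.ch_q))
    elif ev.kind == "translocation":
        src, dst = ev.detail
        i = find(src)
        s = chroms.pop(i)
        moved = s.segments[-1]
        chroms.append(Chromosome(s.segments[:-1],
                                 centromere=min(s.centromere,
                                                len(s.segments) - 1),
                                 ch_p=s.ch_p, ch_q=s.ch_q))
        j = find(dst)
        d = chroms.pop(j)
        chroms.append(Chromosome(d.segments + (moved,),
                                 centromere=d.centromere,
                                 ch_p=d.ch_p, ch_q=d.ch_q))
    elif ev.kind == "inversion":
        segs, new_cent = ev.detail
        i = find(segs)
        c = chroms.pop(i)
        chroms.append(dataclasses.replace(c, centromere=new_cent))
    elif ev.kind == "ch":
        segs, gain = ev.detail
        i = find(segs)
        c = chroms.pop(i)
        chroms.append(dataclasses.replace(c, ch_p=bool(gain)))
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")
    return SimKaryotype(tuple(_sorted_chromosomes(chroms)))


def _draw_event(k: SimKaryotype, kind: str, rng) -> SimEvent | None:
    chroms = k.chromosomes
    if kind == "fission":
        cands = [c for c in chroms if len(c.segments) >= 2]
        if not cands:
            return None
        c = cands[int(rng.integers(len(cands)))]
        cut = int(rng.integers(1, len(c.segments)))
        return SimEvent("fission", (c.segments, cut))
    if kind == "fusion":
        if len(chroms) < 2:
            return None
        i, j = map(int, rng.choice(len(chroms), size=2, replace=False))
        return SimEvent("fusion", (chroms[i].segments, chroms[j].segments))
    if kind == "translocation":
        srcs = [c for c in chroms if len(c.segments) >= 2]
        if not srcs or len(chroms) < 2:
            return None
        s = srcs[int(rng.integers(len(srcs)))]
        others = [c for c in chroms if c is not s]
        d = others[int(rng.integers(len(others)))]
        return SimEvent("translocation", (s.segments, d.segments))
    if kind == "inversion":
        c = chroms[int(rng.integers(len(chroms)))]
        choices = [p for p in range(len(c.segments) + 1) if p != c.centromere]
        if not choices:
            return None
        return SimEvent("inversion",
                        (c.segments, choices[int(rng.integers(len(choices)))]))
    if kind == "ch":
        c = chroms[int(rng.integers(len(chroms)))]
        return SimEvent("ch", (c.segments, not c.ch_p))
    raise ValueError(kind)


def evolve_on_tree(ancestor: SimKaryotype, tree: PhyloTree,
                   rates: dict[str, float] | None = None, seed: int = 0
                   ) -> tuple[HomologyTable, dict[str, KaryotypeDescriptor],
                              EventLog, SegmentRegistry]:
    """Evolve ``ancestor`` along a rooted tree (branch lengths default 1).

    Per branch and event type, counts are Poisson(rate x length); the drawn
    events are applied in shuffled order.  An event that cannot apply (e.g.
    fusion with one chromosome left) is replaced by a draw from the types
    that can, and noted in the log.  Returns the tip homology table,
    descriptors, the event log (replayable to the tips bit-exactly) and the
    segment registry for the simulated blocks.
    """
    if rates is None:
        rates = DEFAULT_RATES
    if not tree.rooted:
        raise ValueError("evolve_on_tree expects a rooted tree")
    bad = {k: v for k, v in rates.items() if v < 0}
    if bad:
        raise ValueError(f"negative rates: {bad}")
    rng = np.random.default_rng(seed)
    log = EventLog(ancestor=ancestor)
    tips: dict[str, SimKaryotype] = {}

    def walk(node: Node, state: SimKaryotype) -> None:
        if node is not tree.root:
            length = node.length if node.length is not None else 1.0
            drawn: list[str] = []
            for kind, rate in sorted(rates.items()):
                drawn += [kind] * int(rng.poisson(rate * length))
            rng.shuffle(drawn)
            events: list[SimEvent] = []
            for kind in drawn:
                ev = _draw_event(state, kind, rng)
                if ev is None:
                    applicable = [t for t in sorted(rates)
                                  if _can_apply(state, t)]
                    if not applicable:
                        log.notes.append(f"no applicable event for {kind}")
                        continue
                    alt = applicable[int(rng.integers(len(applicable)))]
                    log.notes.append(f"resampled {kind} -> {alt}")
                    ev = _draw_event(state, alt, rng)
                    if ev is None:
                        continue
                events.append(ev)
                state = apply_event(state, ev)
            clade = frozenset(n.label for n in node.walk() if n.is_leaf)
            log.branches[clade] = events
        if node.is_leaf:
            tips[node.label] = state
        for c in node.children:
            walk(c, state)

    walk(tree.root, ancestor)
    table, descriptors, registry = _tips_to_table(tips, ancestor)
    return table, descriptors, log, registry


def _can_apply(k: SimKaryotype, kind: str) -> bool:
    if kind == "fission":
        return any(len(c.segments) >= 2 for c in k.chromosomes)
    if kind == "fusion":
        return len(k.chromosomes) >= 2
    if kind == "translocation":
        return len(k.chromosomes) >= 2 and any(
            len(c.segments) >= 2 for c in k.chromosomes)
    if kind == "inversion":
        return any(len(c.segments) >= 1 for c in k.chromosomes)
    return True


def replay(log: EventLog, tree: PhyloTree) -> dict[str, SimKaryotype]:
    """Re-apply the event log from the ancestor; returns tip karyotypes."""
    tips: dict[str, SimKaryotype] = {}

    def walk(node: Node, state: SimKaryotype) -> None:
        if node is not tree.root:
            clade = frozenset(n.label for n in node.walk() if n.is_leaf)
            for ev in log.branches.get(clade, []):
                state = apply_event(state, ev)
        if node.is_leaf:
            tips[node.label] = state
        for c in node.children:
            walk(c, state)

    walk(tree.root, log.ancestor)
    return tips


def _tips_to_table(tips: dict[str, SimKaryotype], ancestor: SimKaryotype):
    blocks = sorted(ancestor.segments)
    probes = tuple(blocks)
    entries: dict[tuple[str, str], list[SignalLocus]] = {}
    descriptors: dict[str, KaryotypeDescriptor] = {}
    placement: dict[str, dict[str, str]] = {b: {} for b in blocks}
    taxa = tuple(sorted(tips))
    for taxon, k in tips.items():
        morphs: dict[str, str] = {}
        ch: list[tuple[str, str]] = []
        for num, c in enumerate(k.chromosomes, start=1):
            label = str(num)
            morphs[label] = c.morphology
            if c.ch_p:
                ch.append((label, "p"))
            for pos, seg in enumerate(c.segments):
                arm = "p" if pos < c.centromere else "q"
                entries.setdefault((taxon, seg), []).append(SignalLocus(
                    chromosome=label,
                    arm=arm if c.biarmed else "whole",
                    arm_printed=c.biarmed,
                ))
                placement[seg][taxon] = label
        descriptors[taxon] = KaryotypeDescriptor(
            taxon=taxon,
            diploid_number=k.diploid_number,
            fundamental_number=k.fundamental_number,
            chromosome_morphologies=morphs,
            ch_blocks=ch,
        )
    table = HomologyTable(taxa=taxa, entries=entries,
                          descriptors=descriptors, probes=probes)
    table.validate()
    registry = SegmentRegistry(
        segments=tuple(blocks),
        probe={b: b for b in blocks},
        placement=placement,
        taxa=taxa,
        version="simulated",
    )
    return table, descriptors, registry


def _blocks_disjoint(log: EventLog) -> bool:
    """True when no two logged events touch a common block (each change is
    then independently visible at the tips)."""
    seen: set[str] = set()
    for evs in log.branches.values():
        for ev in evs:
            touched: set[str] = set()
            for part in ev.detail:
                if isinstance(part, tuple):
                    touched.update(x for x in part if isinstance(x, str))
            if touched & seen:
                return False
            seen |= touched
    return True


# ---------------------------------------------------------------------------
# recovery experiment

def random_tree(n_tips: int, seed: int = 0) -> PhyloTree:
    """Random rooted binary shape (uniform coalescent-style joins),
    branch lengths 1."""
    rng = np.random.default_rng(seed)
    nodes = [Node(label=f"T{i + 1}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(map(int, rng.choice(len(nodes), size=2, replace=False)))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(Node(children=[a, b]))
    return PhyloTree(nodes[0], rooted=True)


def recovery_experiment(n_tips: int = 8, replicates: int = 20,
                        rates: dict[str, float] | None = None,
                        n_blocks: int = 26, n_chromosomes: int = 22,
                        seed: int = 0, *, search_starts: int = 4,
                        exact_below: int = 10) -> dict:
    """Simulate -> code -> MP search -> compare, per replicate.

    Reports, per replicate, the Robinson-Foulds distance between the strict
    consensus of the best trees and the true topology, and whether the
    tree-based event tally recovers the true fusion/fission + translocation
    count; plus summary statistics.  Replicates with too little variation to
    be informative are reported as such rather than scored.
    """
    from .coding import build_character_matrix
    from .parsimony import (branch_and_bound_search, rf_distance,
                            strict_consensus, tbr_heuristic_search)
    from .rearrange import tree_event_tally

    results = []
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        anc = simulate_ancestor(n_blocks, n_chromosomes,
                                seed=int(rng.integers(2 ** 31)))
        tree = random_tree(n_tips, seed=int(rng.integers(2 ** 31)))
        table, desc, log, registry = evolve_on_tree(
            anc, tree, rates=rates, seed=int(rng.integers(2 ** 31)))
        try:
            matrix = build_character_matrix(table)
        except ValueError:
            matrix = None
        if matrix is None or matrix.n_characters == 0:
            results.append({"replicate": rep, "informative": False,
                            "n_events": log.n_events})
            continue
        # exact search at small sizes so the complete optimal set (hence any
        # unresolvable split's every resolution) is in hand
        if n_tips <= exact_below:
            res = branch_and_bound_search(matrix)
        else:
            res = tbr_heuristic_search(matrix, n_random_starts=search_starts,
                                       seed=int(rng.integers(2 ** 31)))
        cons = strict_consensus(res.trees)
        true_unrooted = PhyloTree(tree.root.copy(), rooted=False)
        # rf: does the MP tree set recover the truth (closest best tree);
        # rf_consensus additionally penalizes lack of resolution
        rf = min(rf_distance(t, true_unrooted) for t in res.trees)
        rf_consensus = rf_distance(cons, true_unrooted)

        tally = tree_event_tally(table, taxa=table.taxa, tree=tree,
                                 registry=registry)
        true_ff = (log.count("fission") + log.count("fusion"))
        true_tl = log.count("translocation")
        results.append({
            "replicate": rep, "informative": True, "rf": rf,
            "rf_consensus": rf_consensus,
            "event_blocks_disjoint": _blocks_disjoint(log),
            "n_events": log.n_events,
            "tally_fusion_fission": tally.fusion_fission,
            "tally_translocation": tally.translocation,
            "true_fusion_fission": true_ff,
            "true_translocation": true_tl,
        })
    rfs = sorted(r["rf"] for r in results if r.get("informative"))
    summary = {
        "replicates": replicates,
        "informative": len(rfs),
        "median_rf": (rfs[len(rfs) // 2] if rfs else None),
        "exact_tally": sum(
            1 for r in results if r.get("informative")
            and r["tally_fusion_fission"] == r["true_fusion_fission"]
            and r["tally_translocation"] == r["true_translocation"]),
    }
    return {"summary": summary, "replicates": results}
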