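"""Shared fixtures and independent brute-force oracles.

The oracles here never call the implementation paths they check: tree
length is minimized over explicit ancestral state assignments, topologies
are enumerated recursively, and partition edit distance is found by
breadth-first search over partition space.
"""

from __future__ import annotations

import itertools
import random

import pytest

from karyophy.coding import CharacterDefinition, CharacterMatrix
from karyophy.painting import load_homology_table
from karyophy.trees import PhyloTree

NEACOMYS = frozenset(["NSP-A", "NSP-B", "NSP-C", "NSP-D", "NPA", "NSP-E", "NAM"])
AKODONTINI = frozenset(["TNI", "AMO", "ASP", "NLA"])


@pytest.fixture(scope="session")
def table():
    return load_homology_table()


@pytest.fixture(scope="session")
def matrix(table):
    from karyophy.coding import build_character_matrix
    return build_character_matrix(table)


@pytest.fixture(scope="session")
def fixture_search(matrix):
    """One heuristic search on the coded fixture, shared across tests."""
    from karyophy.parsimony import tbr_heuristic_search
    return tbr_heuristic_search(matrix, n_random_starts=6, seed=1)


def random_matrix(rng: random.Random, ntax: int, nchar: int,
                  nstates: int = 3, missing: float = 0.0) -> CharacterMatrix:
    taxa = [f"T{i}" for i in range(ntax)]
    defs, states = [], [[] for _ in taxa]
    for j in range(nchar):
        col = [rng.randrange(nstates) for _ in taxa]
        if missing and rng.random() < missing:
            col[rng.randrange(ntax)] = None
        obs = sorted({c for c in col if c is not None})
        if not obs:
            continue
        remap = {s: i for i, s in enumerate(obs)}
        col = [None if c is None else remap[c] for c in col]
        defs.append(CharacterDefinition(
            f"c{j}", tuple(str(s) for s in range(len(obs)))))
        for i in range(ntax):
            states[i].append(col[i])
    if not defs:  # ensure at least one character
        defs = [CharacterDefinition("c0", ("0", "1"))]
        for i in range(ntax):
            states[i].append(i % 2)
    return CharacterMatrix(taxa, defs, states)


def all_topologies(labels):
    """Every unrooted binary topology as a nested 3-child tuple."""
    labels = list(labels)
    if len(labels) == 3:
        yield tuple(labels)
        return
    *rest, last = labels

    def insertions(node):
        yield (last, node)
        if isinstance(node, tuple) and len(node) == 2:
            for k, child in enumerate(node):
                for alt in insertions(child):
                    lst = list(node)
                    lst[k] = alt
                    yield tuple(lst)

    for t in all_topologies(rest):
        for k, child in enumerate(t):
            for alt in insertions(child):
                lst = list(t)
                lst[k] = alt
                yield tuple(lst)


def brute_force_length(topo, matrix: CharacterMatrix) -> int:
    """Minimum changes over all explicit internal-state assignments."""
    internals = []

    def collect(node):
        if isinstance(node, tuple):
            internals.append(node)
            for c in node:
                collect(c)

    collect(topo)
    total = 0
    for j in range(matrix.n_characters):
        col = matrix.column(j)
        ns = len(matrix.characters[j].state_labels)
        best = None
        for assign in itertools.product(range(ns), repeat=len(internals)):
            amap = dict(zip(map(id, internals), assign))
            cost = 0

            def edges(node, parent_state):
                nonlocal cost
                if isinstance(node, tuple):
                    st = amap[id(node)]
                    if parent_state is not None and st != parent_state:
                        cost += 1
                    for c in node:
                        edges(c, st)
                else:
                    st = col[node]
                    if st is not None and st != parent_state:
                        cost += 1

            edges(topo, None)
            best = cost if best is None else min(best, cost)
        total += best
    return total


def bfs_partition_distance(p: tuple, q: tuple) -> int:
    """Shortest split/merge path between two partitions (frozenset of
    frozensets), by breadth-first search."""
    start = frozenset(p)
    goal = frozenset(q)
    if start == goal:
        return 0
    frontier = {start}
    seen = {start}
    dist = 0
    while frontier:
        dist += 1
        nxt = set()
        for part in frontier:
            for nb in _partition_neighbors(part):
                if nb == goal:
                    return dist
                if nb not in seen:
                    seen.add(nb)
                    nxt.add(nb)
        frontier = nxt
    raise AssertionError("partition space is connected")


def _partition_neighbors(part):
    groups = list(part)
    # merges
    for a, b in itertools.combinations(groups, 2):
        yield frozenset([g for g in groups if g not in (a, b)] + [a | b])
    # splits (all 2-way)
    for g in groups:
        members = sorted(g)
        if len(members) < 2:
            continue
        rest = [x for x in groups if x != g]
        for r in range(1, len(members)):
            for left in itertools.combinations(members, r):
                if members[0] not in left:
                    continue  # avoid double-counting complements
                l = frozenset(left)
                yield frozenset(rest + [l, g - l])
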