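"""Partition distances, ancestral-partition event tally, and morphology
event classification."""

import itertools
import random

import pytest

from conftest import bfs_partition_distance
from karyophy.painting import PaintingError
from karyophy.rearrange import (BlockPartition, NEACOMYS_KARYOTYPES,
                                chromosome_partition, load_segment_registry,
                                neacomys_ingroup_tree, partition_edit_distance,
                                tree_event_tally)
from karyophy.trees import PhyloTree


def _bp(name, *groups):
    return BlockPartition(name, tuple(frozenset(g) for g in groups))


def test_registry_loads_and_matches_table(table):
    reg = load_segment_registry()
    assert len(reg.taxa) == 7
    for taxon in NEACOMYS_KARYOTYPES:
        part = chromosome_partition(table, taxon, reg)
        assert part.universe == frozenset(reg.segments)


def test_partition_group_counts_match_karyotypes(table):
    # painted chromosome groups: autosome pairs + X
    assert len(chromosome_partition(table, "NPA")) == 28
    assert len(chromosome_partition(table, "NSP-E")) == 31


def test_registry_missing_taxon_is_named(table):
    reg = load_segment_registry()
    with pytest.raises(KeyError):
        reg.partition("CLA")


def test_singleton_partition():
    p = _bp("t", *[[f"s{i}"] for i in range(5)])
    assert len(p) == 5
    assert partition_edit_distance(p, p) == (0, 0)


def test_edit_distance_simple_cases():
    p = _bp("p", ["A", "B"], ["C"])
    q = _bp("q", ["A"], ["B", "C"])
    assert partition_edit_distance(p, q) == (1, 1)
    r = _bp("r", ["A", "B", "C"])
    assert partition_edit_distance(p, r) == (0, 1)
    assert partition_edit_distance(r, p) == (1, 0)


def test_universe_mismatch():
    with pytest.raises(ValueError, match="universes"):
        partition_edit_distance(_bp("p", ["A"]), _bp("q", ["B"]))


def _random_partition(rng, items):
    groups = []
    for x in items:
        if groups and rng.random() < 0.6:
            groups[rng.randrange(len(groups))].append(x)
        else:
            groups.append([x])
    return _bp("r", *groups)


def test_edit_distance_equals_bfs_oracle():
    rng = random.Random(19)
    items = [f"s{i}" for i in range(6)]
    for trial in range(25):
        p = _random_partition(rng, items)
        q = _random_partition(rng, items)
        fis, fus = partition_edit_distance(p, q)
        want = bfs_partition_distance(
            tuple(p.groups), tuple(q.groups))
        assert fis + fus == want, (trial, p.groups, q.groups)


def test_edit_distance_metric_axioms():
    rng = random.Random(29)
    items = [f"s{i}" for i in range(7)]
    parts = [_random_partition(rng, items) for _ in range(8)]

    def d(a, b):
        return sum(partition_edit_distance(a, b))

    for a, b in itertools.combinations(parts, 2):
        assert d(a, b) == d(b, a)
        assert (d(a, b) == 0) == (set(a.groups) == set(b.groups))
    for a, b, c in itertools.combinations(parts, 3):
        assert d(a, c) <= d(a, b) + d(b, c)


def test_identical_karyotypes_zero_tally(table):
    """NSP-C and NSP-D have identical segment partitions; a cherry over
    them yields an all-zero fusion/fission tally."""
    reg = load_segment_registry()
    tree = PhyloTree.from_nested(("NSP-C", "NSP-D"), rooted=True)
    tally = tree_event_tally(table, taxa=("NSP-C", "NSP-D"), tree=tree,
                             registry=reg)
    assert tally.fusion_fission == 0
    assert tally.translocation == 0


def test_headline_tally(table):
    """Seven karyotypes on the published ingroup topology: 17 distinct
    fusion/fission events and one translocation."""
    tally = tree_event_tally(table)
    assert tally.fusion_fission == 17
    assert tally.translocation == 1
    # the translocation is the probe-5 segment entering NSP-B's complex
    (tl,) = [e for e in tally.events if e.kind == "translocation"]
    assert tl.parts[0] == frozenset({"5d"})


def test_tally_invariant_to_taxon_input_order(table):
    t1 = tree_event_tally(table, taxa=NEACOMYS_KARYOTYPES)
    t2 = tree_event_tally(table, taxa=tuple(reversed(NEACOMYS_KARYOTYPES)))
    assert t1.fusion_fission == t2.fusion_fission
    assert t1.translocation == t2.translocation


def test_branch_moves_bound_pairwise_distances(table):
    """Total per-branch moves upper-bound every tip pair's partition
    distance (parsimony lower-bound consistency)."""
    reg = load_segment_registry()
    tally = tree_event_tally(table)
    parts = {t: chromosome_partition(table, t, reg, include_x=False)
             for t in NEACOMYS_KARYOTYPES}
    for a, b in itertools.combinations(NEACOMYS_KARYOTYPES, 2):
        assert sum(partition_edit_distance(parts[a], parts[b])) \
            <= tally.total_moves


def test_morphology_classification(table):
    """NSP-C vs NSP-D differ only by CH arms on three pairs, so the blocks
    they carry (HME 5, 11, 23) are CH-changed, the X varies by CH, and no
    same-content morphological difference remains for inversion."""
    tally = tree_event_tally(table)
    assert tally.ch_changed_blocks == {"5", "11", "23"}
    assert tally.x_ch_changed
    assert tally.inverted_blocks == set()


def test_tree_taxon_mismatch(table):
    tree = PhyloTree.from_nested(("NSP-C", "NSP-D"), rooted=True)
    with pytest.raises(ValueError, match="leaves"):
        tree_event_tally(table, taxa=NEACOMYS_KARYOTYPES, tree=tree)
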