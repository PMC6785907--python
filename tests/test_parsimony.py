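"""Parsimony engine vs independent brute-force oracles."""

import itertools
import random

import pytest

from conftest import all_topologies, brute_force_length, random_matrix
from karyophy.coding import CharacterDefinition, CharacterMatrix
from karyophy.parsimony import (BootstrapOptions, bootstrap_support,
                                branch_and_bound_search, character_fits,
                                ensemble_indices, fitch_length, rf_distance,
                                strict_consensus, tbr_heuristic_search)
from karyophy.trees import PhyloTree


def test_fitch_equals_assignment_oracle_small():
    """Tree length equals the minimum over all explicit ancestral state
    assignments, on random <=6-taxon matrices with missing data."""
    rng = random.Random(11)
    for trial in range(60):
        ntax = rng.choice([4, 5, 6])
        m = random_matrix(rng, ntax, rng.choice([3, 4, 5]),
                          rng.choice([2, 3]), missing=0.3)
        topos = list(all_topologies(list(m.taxa)))
        topo = topos[rng.randrange(len(topos))]
        tree = PhyloTree.from_nested(topo)
        got, per_char = fitch_length(tree, m)
        assert got == brute_force_length(topo, m), (trial, topo)
        assert got == sum(per_char)


def test_fitch_invariant_to_rerooting():
    rng = random.Random(5)
    m = random_matrix(rng, 6, 5, 3)
    tree = PhyloTree.from_nested(("T0", ("T1", ("T2", "T3")), ("T4", "T5")))
    base, _ = fitch_length(tree, m)
    rooted = PhyloTree.from_nested(
        ((("T0", ("T1", ("T2", "T3"))), ("T4", "T5"))), rooted=True)
    re_rooted, _ = fitch_length(rooted, m)
    assert base == re_rooted


def test_fitch_constant_character_is_free():
    m = CharacterMatrix(
        ["A", "B", "C", "D"],
        [CharacterDefinition("const", ("0",)),
         CharacterDefinition("var", ("0", "1"))],
        [[0, 0], [0, 0], [0, 1], [0, 1]])
    tree = PhyloTree.from_nested(("A", "B", ("C", "D")))
    total, per_char = fitch_length(tree, m)
    assert per_char[0] == 0 and total == 1


def test_fitch_polytomy_scored_as_given():
    # star tree: every non-majority leaf state costs a change
    m = CharacterMatrix(["A", "B", "C", "D"],
                        [CharacterDefinition("c", ("0", "1"))],
                        [[0], [0], [1], [1]])
    star = PhyloTree.from_nested(("A", "B", "C", "D"))
    bifurcating = PhyloTree.from_nested(("A", "B", ("C", "D")))
    assert fitch_length(star, m)[0] == 2
    assert fitch_length(bifurcating, m)[0] == 1


def test_leaf_mismatch_reported():
    m = CharacterMatrix(["A", "B", "C"], [CharacterDefinition("c", ("0", "1"))],
                        [[0], [0], [1]])
    tree = PhyloTree.from_nested(("A", "B", "X"))
    with pytest.raises(ValueError, match="X"):
        fitch_length(tree, m)


def test_branch_and_bound_equals_exhaustive_7_taxa():
    """B&B returns exactly the optimal tree set found by scoring every
    unrooted 7-taxon topology."""
    rng = random.Random(23)
    for trial in range(2):
        m = random_matrix(rng, 7, 7, 3)
        scored = [(fitch_length(PhyloTree.from_nested(t), m)[0], t)
                  for t in all_topologies(list(m.taxa))]
        best = min(s for s, _ in scored)
        best_sigs = {frozenset(PhyloTree.from_nested(t).splits())
                     for s, t in scored if s == best}
        res = branch_and_bound_search(m)
        assert res.score == best
        assert {frozenset(t.splits()) for t in res.trees} == best_sigs


def test_branch_and_bound_trivial_split():
    m = CharacterMatrix(["A", "B", "C", "D"],
                        [CharacterDefinition("c", ("0", "1"))],
                        [[0], [0], [1], [1]])
    res = branch_and_bound_search(m)
    assert res.score == 1
    assert len(res.trees) == 1
    assert res.trees[0].is_monophyletic({"A", "B"})


def test_branch_and_bound_refuses_large():
    m = random_matrix(random.Random(0), 19, 3, 2)
    with pytest.raises(ValueError, match="heuristic"):
        branch_and_bound_search(m)


def test_tbr_matches_exact_search():
    rng = random.Random(31)
    for trial in range(4):
        m = random_matrix(rng, rng.choice([7, 8]), 8, 3)
        exact = branch_and_bound_search(m)
        heur = tbr_heuristic_search(m, n_random_starts=5, seed=trial)
        assert heur.score == exact.score


def test_tbr_recovers_perfect_phylogeny():
    # compatible binary characters: length = sum(m), the true tree recovered
    m = CharacterMatrix(
        ["A", "B", "C", "D", "E", "F"],
        [CharacterDefinition(f"c{i}", ("0", "1")) for i in range(3)],
        [[0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]])
    res = tbr_heuristic_search(m, n_random_starts=4, seed=0)
    assert res.score == sum(f.m for f in character_fits(res.trees[0], m))
    ei = ensemble_indices(res.trees[0], m)
    assert ei.ci == 1.0 and ei.hi == 0.0


def test_fit_bounds_and_index_identities():
    rng = random.Random(41)
    for trial in range(20):
        m = random_matrix(rng, 6, 6, 3, missing=0.2)
        topos = list(all_topologies(list(m.taxa)))
        tree = PhyloTree.from_nested(topos[rng.randrange(len(topos))])
        fits = character_fits(tree, m)
        for f in fits:
            assert 0 <= f.m <= f.s <= f.g
        if sum(f.s for f in fits) == 0:
            continue
        ei = ensemble_indices(tree, m)
        assert 0 <= ei.ci <= 1 and 0 <= ei.ri <= 1 and 0 <= ei.hi <= 1
        assert ei.hi == pytest.approx(1 - ei.ci)


def test_max_steps_independent_recount():
    """g equals taxa-with-state minus largest class, recomputed here."""
    rng = random.Random(17)
    m = random_matrix(rng, 6, 8, 3, missing=0.3)
    tree = PhyloTree.from_nested(next(all_topologies(list(m.taxa))))
    fits = character_fits(tree, m)
    for j, f in enumerate(fits):
        col = [s for s in m.column(j).values() if s is not None]
        counts = {s: col.count(s) for s in set(col)}
        assert f.g == len(col) - max(counts.values())
        assert f.m == len(counts) - 1


def test_ci_undefined_for_all_constant():
    m = CharacterMatrix(["A", "B", "C", "D"],
                        [CharacterDefinition("c", ("0", "1"))],
                        [[0], [0], [0], [None]])
    tree = PhyloTree.from_nested(("A", "B", ("C", "D")))
    with pytest.raises(ValueError, match="CI"):
        ensemble_indices(tree, m)


def test_strict_consensus_singleton_and_intersection():
    t1 = PhyloTree.from_newick("((A,B),(C,D),E);")
    assert strict_consensus([t1]).splits() == t1.splits()
    t2 = PhyloTree.from_newick("((A,B),C,(D,E));")
    cons = strict_consensus([t1, t2])
    assert cons.splits() == t1.splits() & t2.splits()
    assert cons.is_monophyletic({"A", "B"})


def test_consensus_leafset_mismatch():
    t1 = PhyloTree.from_newick("(A,B,C);")
    t2 = PhyloTree.from_newick("(A,B,D);")
    with pytest.raises(ValueError, match="leaf sets"):
        strict_consensus([t1, t2])


def test_rf_distance_vs_split_enumeration():
    rng = random.Random(13)
    labels = [f"T{i}" for i in range(8)]
    topos = list(all_topologies(labels))
    for _ in range(10):
        a = PhyloTree.from_nested(topos[rng.randrange(len(topos))])
        b = PhyloTree.from_nested(topos[rng.randrange(len(topos))])
        assert rf_distance(a, b) == len(a.splits() ^ b.splits())
        assert rf_distance(a, a) == 0
    c = PhyloTree.from_newick("((A,B),(C,D));")
    d = PhyloTree.from_newick("((A,C),(B,D));")
    assert rf_distance(c, d) == 2


def test_bootstrap_clean_split_and_seed_stability():
    m = CharacterMatrix(
        ["A", "B", "C", "D", "E"],
        [CharacterDefinition(f"c{i}", ("0", "1")) for i in range(4)],
        [[0] * 4, [0] * 4, [1] * 4, [1] * 4, [1] * 4])
    bs = bootstrap_support(m, replicates=40, seed=3)
    assert bs[frozenset({"C", "D", "E"})] == pytest.approx(100.0)
    assert frozenset(m.taxa) not in bs  # trivial clade never reported

    rng = random.Random(3)
    m2 = random_matrix(rng, 6, 12, 2)
    a = bootstrap_support(m2, replicates=120, seed=1,
                          search=BootstrapOptions(exact_below=8))
    b = bootstrap_support(m2, replicates=120, seed=2,
                          search=BootstrapOptions(exact_below=8))
    for split in set(a) & set(b):
        if max(a[split], b[split]) > 20:
            assert abs(a[split] - b[split]) < 15  # sampling error only
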