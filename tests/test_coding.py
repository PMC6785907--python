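"""Character coding: determinism, information content, and matrix IO."""

import random

import pytest

from karyophy import painting as P
from karyophy.coding import (CharacterDefinition, CharacterMatrix,
                             CodingScheme, association_pairs,
                             block_configuration, build_character_matrix,
                             load_character_matrix, save_character_matrix)


def test_block_configuration_solo_and_copainted(table):
    n, items = block_configuration(table, "NSP-C", "12")
    assert n == 1
    (companions, ts, morph) = items[0]
    assert companions == ("(16,17)",)  # 12/(16,17) on one chromosome
    n, items = block_configuration(table, "NPA", "2")
    assert n == 1 and items[0][0] == ()  # intact solo block


def test_identical_cells_give_identical_keys(table):
    # NSP-C and NSP-D probe 2 cells are identical and solo
    assert (block_configuration(table, "NSP-C", "2")
            == block_configuration(table, "NSP-D", "2"))


def test_matrix_dimensions_and_determinism(table, matrix):
    assert matrix.taxa == table.taxa
    assert matrix.n_characters > 50
    again = build_character_matrix(table)
    assert again == matrix


def test_signature_pairs_are_neacomys_synapomorphies(table, matrix):
    """The four genus motifs appear as shared derived states of the seven
    Neacomys columns: each motif's pairs are present in all seven and in no
    other taxon except where the study itself notes homoplasy."""
    nea = ["NSP-A", "NSP-B", "NSP-C", "NSP-D", "NPA", "NSP-E", "NAM"]
    for a, b in [("(13,22)", "20"), ("(13,22)", "4"),
                 ("(16,17)", "12"), ("21", "6")]:
        label = f"association HME {a}/{b}"
        j = next(i for i, c in enumerate(matrix.characters) if c.label == label)
        col = matrix.column(j)
        labels = matrix.characters[j].state_labels
        present = {t for t, s in col.items()
                   if s is not None and labels[s] == "present"}
        assert set(nea) <= present, (a, b, present)


def test_taxon_order_only_renumbers_states(table):
    m1 = build_character_matrix(table)
    # rebuild with reversed taxon order
    t2 = P.HomologyTable(
        taxa=tuple(reversed(table.taxa)),
        entries=table.entries,
        descriptors=table.descriptors,
        probes=table.probes,
    )
    m2 = build_character_matrix(t2)
    by_label_1 = {c.label: j for j, c in enumerate(m1.characters)}
    by_label_2 = {c.label: j for j, c in enumerate(m2.characters)}
    assert set(by_label_1) == set(by_label_2)
    for label in by_label_1:
        assert (m1.column_partition(by_label_1[label])
                == m2.column_partition(by_label_2[label])), label


def test_identical_taxa_identical_rows(table):
    # NSP-C and NSP-D share every cell except probes 5, 14, 19, 23 and their
    # descriptors; restrict to characters untouched by those blocks
    m = build_character_matrix(table, CodingScheme(include_morphology=False))
    touched = {"5", "14", "19", "23"}
    for j, c in enumerate(m.characters):
        if any(f"HME {b}" in c.label or f"{b}/" in c.label or f"/{b}" in c.label
               for b in touched):
            continue
        col = m.column(j)
        assert col["NSP-C"] == col["NSP-D"], c.label


def test_simulated_single_fission_varies_only_touched_blocks():
    from karyophy.simulate import (SimEvent, apply_event, random_tree,
                                   simulate_ancestor, evolve_on_tree)
    anc = simulate_ancestor(10, 6, seed=3)
    tree = random_tree(4, seed=1)
    table, _, log, _ = evolve_on_tree(
        anc, tree, rates={"fission": 0.0, "fusion": 0.0, "inversion": 0.0,
                          "translocation": 0.0, "ch": 0.0}, seed=0)
    # force one fission on one terminal branch
    big = max(anc.chromosomes, key=lambda c: len(c.segments))
    ev = SimEvent("fission", (big.segments, 1))
    tip = sorted(table.taxa)[0]
    karyos = {t: anc for t in table.taxa}
    karyos[tip] = apply_event(anc, ev)
    from karyophy.simulate import _tips_to_table
    table2, _, _ = _tips_to_table(karyos, anc)
    m = build_character_matrix(table2, CodingScheme(include_morphology=False))
    touched = set(big.segments)
    for j, c in enumerate(m.characters):
        assert not m.is_constant(j)
        assert touched & {tok for tok in c.label.replace("association HME ", "")
                          .replace("configuration of block HME ", "").split("/")}, c.label


def test_nexus_and_tnt_round_trip(matrix, tmp_path):
    for dialect in ("nexus", "tnt"):
        path = tmp_path / f"m.{dialect}"
        save_character_matrix(matrix, path, dialect)
        again = load_character_matrix(path, dialect)
        assert again.taxa == matrix.taxa
        assert again.states == matrix.states


def test_handwritten_nexus():
    text = """#NEXUS
BEGIN CHARACTERS;
  DIMENSIONS NTAX=4 NCHAR=3;
  FORMAT DATATYPE=STANDARD SYMBOLS="0 1 2" MISSING=?;
  MATRIX
    A 012
    B 0?2
    C 110
    D 210
  ;
END;
"""
    import pathlib
    import tempfile
    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "x.nex"
        p.write_text(text)
        m = load_character_matrix(p)
    assert m.taxa == ("A", "B", "C", "D")
    assert m.n_characters == 3
    assert m.row("B")[1] is None
    assert m.column_partition(0) == frozenset(
        [frozenset({"A", "B"}), frozenset({"C"}), frozenset({"D"})])


def test_header_mismatch_rejected(tmp_path):
    bad = "#NEXUS\nBEGIN CHARACTERS;\nDIMENSIONS NTAX=3 NCHAR=2;\nMATRIX\nA 01\nB 10\n;\nEND;\n"
    p = tmp_path / "bad.nex"
    p.write_text(bad)
    with pytest.raises(ValueError, match="3 taxa"):
        load_character_matrix(p)
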