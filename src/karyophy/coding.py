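"""Coding homology tables into non-additive multistate character matrices.

Chromosomal characters here are qualitative, unordered and unweighted:
rearrangements are rare events with strong phylogenetic signal, and no cost
structure is imposed between states.  Three kinds of characters are coded
from a homology table:

* ``block-configuration`` -- one character per probe; its state is a
  canonical key describing how that probe's block is distributed: how many
  signals, which other probes co-paint each target chromosome, and which
  signals are two-segment.
* ``association`` -- one binary character per pair of probes observed
  co-painting a single chromosome in at least one taxon (the currency in
  which chromosomal signatures are reported, e.g. 3/25 or 12/(16,17));
  larger motifs such as 20/(13,22)/4 are chains of these pairs.
* ``morphology`` -- per probe, the morphology classes (acrocentric vs
  bi-armed) of its carrying chromosomes, where descriptors record them;
  missing otherwise.

States are numbered by first appearance over a fixed taxon order, so coding
is deterministic; permuting input taxa permutes state numbers but never the
partition of taxa into state classes.

External matrices are read and written in NEXUS (CHARACTERS block) and TNT
(xread) dialects; the published supplementary matrix, where available, is
the authoritative input for reproducing the study's exact tree statistics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .painting import PROBES, HomologyTable, PaintingError

__all__ = [
    "CharacterDefinition", "CharacterMatrix", "CodingScheme",
    "block_configuration", "association_motifs", "build_character_matrix",
    "load_character_matrix", "save_character_matrix",
]

MISSING = "?"
_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class CharacterDefinition:
    """A character: human-readable label, ordered state labels, kind."""

    label: str
    state_labels: tuple[str, ...]
    kind: str = "block-configuration"

    def __post_init__(self):
        if not self.state_labels:
            raise ValueError(f"{self.label}: no states")
        if len(set(self.state_labels)) != len(self.state_labels):
            raise ValueError(f"{self.label}: duplicate state labels")


class CharacterMatrix:
    """Taxa x unordered multistate characters, with '?' for missing."""

    def __init__(self, taxa: Sequence[str],
                 characters: Sequence[CharacterDefinition],
                 states: Sequence[Sequence[int | None]]):
        self.taxa = tuple(taxa)
        self.characters = list(characters)
        self.states = [list(row) for row in states]
        if len(self.states) != len(self.taxa):
            raise ValueError("one state row per taxon required")
        for t, row in zip(self.taxa, self.states):
            if len(row) != len(self.characters):
                raise ValueError(f"{t}: row length != character count")
            for j, s in enumerate(row):
                if s is not None and not (0 <= s < len(self.characters[j].state_labels)):
                    raise ValueError(f"{t} char {j}: state {s} out of range")
        for j in range(self.n_characters):
            if all(row[j] is None for row in self.states):
                raise ValueError(f"character {j} has no observed states")

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str) -> list[int | None]:
        return self.states[self.taxa.index(taxon)]

    def column(self, j: int) -> dict[str, int | None]:
        return {t: self.states[i][j] for i, t in enumerate(self.taxa)}

    def column_partition(self, j: int) -> frozenset:
        """Taxon classes of character j, as a relabeling-invariant partition
        (missing taxa excluded)."""
        groups: dict[int, set[str]] = {}
        for i, t in enumerate(self.taxa):
            s = self.states[i][j]
            if s is not None:
                groups.setdefault(s, set()).add(t)
        return frozenset(frozenset(g) for g in groups.values())

    def is_constant(self, j: int) -> bool:
        seen = {self.states[i][j] for i in range(len(self.taxa))} - {None}
        return len(seen) <= 1

    def drop_constant(self) -> "CharacterMatrix":
        keep = [j for j in range(self.n_characters) if not self.is_constant(j)]
        return self.select(keep)

    def select(self, columns: Sequence[int]) -> "CharacterMatrix":
        return CharacterMatrix(
            self.taxa,
            [self.characters[j] for j in columns],
            [[row[j] for j in columns] for row in self.states],
        )

    def resample(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Column resample (bootstrap replicate); duplicates allowed."""
        return CharacterMatrix(
            self.taxa,
            [self.characters[j] for j in indices],
            [[row[j] for j in indices] for row in self.states],
        )

    def __eq__(self, other) -> bool:
        # data identity: taxa and coded states (labels are annotation)
        return (isinstance(other, CharacterMatrix)
                and self.taxa == other.taxa
                and self.states == other.states)

    def __repr__(self) -> str:
        return f"<CharacterMatrix {len(self.taxa)} taxa x {self.n_characters} characters>"


# ---------------------------------------------------------------------------
# the built-in coder

@dataclass
class CodingScheme:
    include_morphology: bool = True
    drop_invariant: bool = True


def _chromosome_contents(table: HomologyTable, taxon: str) -> dict[str, dict]:
    """chromosome -> {'probes': set, 'ts': set of probes with a ts signal}"""
    out: dict[str, dict] = {}
    for p in table.probes:
        for loc in table.entries[(taxon, p)]:
            d = out.setdefault(loc.chromosome, {"probes": set(), "ts": set()})
            d["probes"].add(p)
            if loc.two_segment:
                d["ts"].add(p)
    return out


def _morphology_class(table: HomologyTable, taxon: str, chromosome: str) -> str:
    d = table.descriptors.get(taxon)
    if d is None:
        return "unknown"
    m = d.chromosome_morphologies.get(chromosome)
    if m is None:
        return "unknown"
    return "acrocentric" if m == "acrocentric" else "biarmed"


def block_configuration(table: HomologyTable, taxon: str, probe: str) -> tuple:
    """Canonical, order-independent configuration key for one probe.

    The key lists, per signal, the set of co-painting probes on the target
    chromosome, the two-segment mark, and the chromosome's morphology class
    ('unknown' when no descriptor records it); signals are sorted so the key
    is independent of cell order.
    """
    signals = table.signals(taxon, probe)
    contents = _chromosome_contents(table, taxon)
    items = []
    for loc in signals:
        companions = frozenset(contents[loc.chromosome]["probes"]) - {probe}
        items.append((tuple(sorted(companions)), loc.two_segment,
                      _morphology_class(table, taxon, loc.chromosome)))
    return (len(signals), tuple(sorted(items)))


def association_motifs(table: HomologyTable) -> list[tuple[str, ...]]:
    """All maximal co-painting probe sets (>= 2 autosomal probes) observed on
    a single chromosome in at least one taxon."""
    motifs: set[tuple[str, ...]] = set()
    for t in table.taxa:
        for chrom, d in _chromosome_contents(table, t).items():
            ps = d["probes"] - {"X"}
            if len(ps) >= 2:
                motifs.add(tuple(sorted(ps)))
    return sorted(motifs)


def association_pairs(table: HomologyTable) -> list[tuple[str, str]]:
    """All unordered autosomal probe pairs co-painting one chromosome in at
    least one taxon."""
    pairs: set[tuple[str, str]] = set()
    for motif in association_motifs(table):
        for a, b in _combinations(motif):
            pairs.add((a, b))
    return sorted(pairs)


def _combinations(items: Sequence[str]):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def build_character_matrix(table: HomologyTable,
                           scheme: CodingScheme | None = None) -> CharacterMatrix:
    """Code a homology table into a multistate character matrix.

    One block-configuration character per probe (X included), one binary
    association character per observed motif, and (optionally) a morphology
    character per motif.  Configuration keys deliberately exclude morphology
    (it is mostly unrecorded for the outgroups and would fragment states);
    morphology variation is carried by the dedicated morphology characters
    where descriptors exist.
    """
    if scheme is None:
        scheme = CodingScheme()
    if not table.taxa:
        raise PaintingError("empty homology table")
    defs: list[CharacterDefinition] = []
    columns: list[list[int | None]] = []  # per character, per taxon

    def add_char(label: str, kind: str, raw: list, labeller=str) -> None:
        codes: dict = {}
        col: list[int | None] = []
        for v in raw:
            if v is None:
                col.append(None)
                continue
            if v not in codes:
                codes[v] = len(codes)
            col.append(codes[v])
        if not codes:
            return
        defs.append(CharacterDefinition(
            label=label, kind=kind,
            state_labels=tuple(labeller(v) for v in codes)))
        columns.append(col)

    # block-configuration characters (keys exclude morphology: see docstring)
    for p in table.probes:
        raw = []
        for t in table.taxa:
            n, items = block_configuration(table, t, p)
            raw.append((n, tuple((c, ts) for c, ts, _m in items)))
        add_char(f"configuration of block HME {p}", "block-configuration", raw,
                 labeller=lambda v: f"{v[0]} signal(s): " + "; ".join(
                     ("+".join(c) if c else "solo") + (" (ts)" if ts else "")
                     for c, ts in v[1]))

    for a, b in association_pairs(table):
        raw = []
        for t in table.taxa:
            contents = _chromosome_contents(table, t)
            has = any({a, b} <= d["probes"] for d in contents.values())
            raw.append(has)
        add_char(f"association HME {a}/{b}", "association", raw,
                 labeller=lambda v: "present" if v else "absent")

    if scheme.include_morphology:
        for p in table.probes:
            if p == "X":
                continue
            raw = []
            for t in table.taxa:
                classes = sorted(
                    _morphology_class(table, t, loc.chromosome)
                    for loc in table.entries[(t, p)])
                raw.append(None if "unknown" in classes else tuple(classes))
            if all(v is None for v in raw):
                continue
            add_char(f"morphology of chromosome(s) bearing HME {p}",
                     "morphology", raw, labeller=lambda v: "+".join(v))

    matrix = CharacterMatrix(table.taxa, defs,
                             [[col[i] for col in columns]
                              for i in range(len(table.taxa))])
    if scheme.drop_invariant:
        matrix = matrix.drop_constant()
    return matrix


# ---------------------------------------------------------------------------
# NEXUS / TNT IO

def save_character_matrix(matrix: CharacterMatrix, path: str | Path,
                          dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "tnt" if path.suffix in (".tnt", ".ss") else "nexus"
    nmax = max(len(c.state_labels) for c in matrix.characters)
    if nmax > len(_SYMBOLS):
        raise ValueError("too many states for symbol set")
    symbols = _SYMBOLS[:nmax]

    def rowtext(row):
        return "".join(MISSING if s is None else _SYMBOLS[s] for s in row)

    if dialect == "nexus":
        lines = ["#NEXUS", "", "BEGIN CHARACTERS;",
                 f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_characters};",
                 f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{' '.join(symbols)}\" MISSING={MISSING};",
                 "  MATRIX"]
        width = max(len(t) for t in matrix.taxa) + 2
        for t, row in zip(matrix.taxa, matrix.states):
            name = f"'{t}'" if re.search(r"[\s(){};,-]", t) else t
            lines.append(f"    {name:<{width}} {rowtext(row)}")
        lines += ["  ;", "END;", ""]
    elif dialect == "tnt":
        lines = ["xread",
                 f"'{matrix.n_characters} unordered multistate chromosomal characters'",
                 f"{matrix.n_characters} {len(matrix.taxa)}"]
        for t, row in zip(matrix.taxa, matrix.states):
            lines.append(f"{t.replace(' ', '_')} {rowtext(row)}")
        lines += [";", ""]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines))


def save_character_definitions(matrix: CharacterMatrix, path: str | Path) -> None:
    """JSON sidecar mapping matrix columns back to chromosomal features."""
    doc = [{"index": j, "label": c.label, "kind": c.kind,
            "state_labels": list(c.state_labels)}
           for j, c in enumerate(matrix.characters)]
    Path(path).write_text(json.dumps(doc, indent=1))


_NEXUS_DIM = re.compile(r"DIMENSIONS[^;]*NTAX\s*=\s*(\d+)[^;]*NCHAR\s*=\s*(\d+)", re.I)
_TNT_HEAD = re.compile(r"xread\s*(?:'[^']*'\s*)?(\d+)\s+(\d+)", re.I)


def load_character_matrix(path: str | Path, dialect: str | None = None) -> CharacterMatrix:
    """Read a NEXUS CHARACTERS/DATA block or TNT xread file.

    Symbols may be alphanumeric; '?' maps to missing.  State labels are the
    symbols themselves (external files carry no feature descriptions).
    """
    path = Path(path)
    text = path.read_text()
    if dialect is None:
        dialect = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "tnt"
    if dialect == "nexus":
        m = _NEXUS_DIM.search(text)
        if not m:
            raise ValueError(f"{path}: no DIMENSIONS line")
        ntax, nchar = int(m.group(1)), int(m.group(2))
        mx = re.search(r"MATRIX(.*?);", text, re.S | re.I)
        if not mx:
            raise ValueError(f"{path}: no MATRIX block")
        body = mx.group(1)
        rows = []
        for line in body.splitlines():
            line = line.strip()
            if not line or line.startswith("["):
                continue
            if line.startswith("'"):
                name, rest = line[1:].split("'", 1)
            else:
                name, rest = (line.split(None, 1) + [""])[:2]
            seq = re.sub(r"\s+", "", rest)
            if name:
                rows.append((name, seq))
    else:
        m = _TNT_HEAD.search(text)
        if not m:
            raise ValueError(f"{path}: no xread header")
        nchar, ntax = int(m.group(1)), int(m.group(2))
        after = text[m.end():]
        after = after.split(";")[0]
        rows = []
        for line in after.splitlines():
            line = line.strip()
            if not line:
                continue
            name, seq = line.split(None, 1)
            rows.append((name, re.sub(r"\s+", "", seq)))
    if len(rows) != ntax:
        raise ValueError(f"{path}: header says {ntax} taxa, found {len(rows)}")
    for name, seq in rows:
        if len(seq) != nchar:
            raise ValueError(f"{path}: {name} has {len(seq)} characters, header says {nchar}")

    taxa = [name for name, _ in rows]
    # per-column symbol -> code, by first appearance down the rows
    columns: list[dict[str, int]] = [dict() for _ in range(nchar)]
    states: list[list[int | None]] = []
    for name, seq in rows:
        row: list[int | None] = []
        for j, sym in enumerate(seq):
            if sym == MISSING or sym == "-":
                row.append(None)
                continue
            col = columns[j]
            if sym not in col:
                col[sym] = len(col)
            row.append(col[sym])
        states.append(row)
    defs = [CharacterDefinition(label=f"character {j + 1}",
                                state_labels=tuple(col) or ("0",),
                                kind="external")
            for j, col in enumerate(columns)]
    return CharacterMatrix(taxa, defs, states)
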