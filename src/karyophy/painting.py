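"""Chromosome-painting homology tables and karyotype descriptors.

Comparative chromosome painting (ZOO-FISH) hybridizes whole-chromosome probes
from a reference species onto the metaphases of another; each hybridization
signal marks a syntenic block.  This module holds the machine-readable form of
such an experiment: for every (karyotype, probe) pair, the list of signal loci
(target chromosome, arm, region qualifiers, two-segment flag), together with
per-karyotype descriptors (diploid number 2n, autosomal fundamental number FN,
chromosome morphologies, constitutive-heterochromatin blocks).

The packaged fixture transcribes the published homology table for 24
*Hylaeamys megacephalus* (HME) whole-chromosome probes (three of them
composite: (9,10), (13,22), (16,17)) hybridized onto 14 sigmodontine
karyotypes, plus the implicit HME reference itself.  Printed column totals
count painted *segments*, so a two-segment signal counts twice; the fixture
embeds the totals as a checksum row and loading verifies them.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROBES",
    "FIXTURE_TAXA",
    "SignalLocus",
    "KaryotypeDescriptor",
    "HomologyTable",
    "PaintingError",
    "IntegrityError",
    "parse_signal_cell",
    "format_signal_cell",
    "load_homology_table",
    "save_homology_table",
    "total_signals",
    "conserved_synteny_probes",
    "association_chromosomes",
    "summary_table",
]

#: The 24 probe labels, in table order.  Composite probes are parenthesized
#: exactly as printed; they derive from two reference chromosomes each.
PROBES: tuple[str, ...] = (
    "1", "2", "3", "4", "5", "6", "7", "8", "(9,10)", "11", "12", "(13,22)",
    "14", "15", "(16,17)", "18", "19", "20", "21", "23", "24", "25", "26", "X",
)

#: Fixture taxon order (reference first); state numbering elsewhere follows it.
FIXTURE_TAXA: tuple[str, ...] = (
    "HME", "CLA", "TNI", "AMO", "ASP", "NLA", "OCA-PA", "OCA-RJ",
    "NSP-A", "NSP-B", "NSP-C", "NSP-D", "NPA", "NSP-E", "NAM",
)

_REGIONS = ("prox", "int", "dist")


class PaintingError(ValueError):
    """Malformed cell text or inconsistent homology table."""


class IntegrityError(PaintingError):
    """Fixture checksum (printed signal totals) violated."""


@dataclass(frozen=True)
class SignalLocus:
    """One hybridization signal: a syntenic block on a target chromosome.

    ``arm`` is 'p', 'q' or 'whole'.  Acrocentric chromosomes have a single
    arm (q, by convention); cells that qualify a region without printing an
    arm letter are parsed with ``arm='q'`` and ``arm_printed=False`` so that
    re-serialization reproduces the original text.  ``two_segment`` mirrors a
    printed "(ts)" mark; a locus also paints two segments when its regions
    are exactly proximal and distal (a disjoint span).
    """

    chromosome: str
    arm: str = "whole"
    regions: tuple[str, ...] = ()
    two_segment: bool = False
    heterochromatic_gap: bool = False
    arm_printed: bool = True

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise PaintingError("empty chromosome label")
        if self.arm not in ("p", "q", "whole"):
            raise PaintingError(f"bad arm {self.arm!r}")
        if self.arm == "whole" and self.regions:
            raise PaintingError("regions require an arm")
        for r in self.regions:
            if r not in _REGIONS:
                raise PaintingError(f"bad region {r!r}")

    @property
    def n_segments(self) -> int:
        """Painted segments this locus contributes (the printed totals'
        counting unit)."""
        if self.two_segment:
            return 2
        if set(self.regions) == {"prox", "dist"}:
            return 2
        return 1


_LOCUS_RE = re.compile(
    r"^(?P<chrom>X|\d+)\s*(?P<arm>[pq])?"
    r"(?:\s+(?P<r1>prox|int|dist)\.(?:\s+and\s+(?P<r2>prox|int|dist)\.)?)?"
    r"(?P<ts>\s*\(ts\))?$"
)


def parse_signal_cell(text: str, *, where: str = "") -> list[SignalLocus]:
    """Parse one homology-table cell into its signal loci.

    Grammar: comma-separated loci; each locus is a chromosome label, an
    optional arm letter, optional region qualifier(s) joined by "and", and an
    optional "(ts)" two-segment mark.  Regions joined by "and" fold into one
    locus.  Raises :class:`PaintingError` naming the offending token.
    """
    loci: list[SignalLocus] = []
    for raw in text.split(","):
        tok = raw.strip()
        if not tok:
            raise PaintingError(f"empty signal token in cell {text!r} {where}")
        m = _LOCUS_RE.match(tok)
        if not m:
            raise PaintingError(f"unrecognized token {tok!r} in cell {text!r} {where}")
        regions = tuple(r for r in (m.group("r1"), m.group("r2")) if r)
        arm = m.group("arm")
        loci.append(
            SignalLocus(
                chromosome=m.group("chrom"),
                arm=arm if arm else ("q" if regions else "whole"),
                regions=regions,
                two_segment=bool(m.group("ts")),
                arm_printed=arm is not None,
            )
        )
    return loci


def format_signal_cell(loci: Sequence[SignalLocus]) -> str:
    """Inverse of :func:`parse_signal_cell` (identity on fixture cells)."""
    parts = []
    for loc in loci:
        s = loc.chromosome
        if loc.arm != "whole" and loc.arm_printed:
            s += loc.arm
        if loc.regions:
            s += " " + " and ".join(f"{r}." for r in loc.regions)
        if loc.two_segment:
            s += " (ts)"
        parts.append(s)
    return ", ".join(parts)


@dataclass
class KaryotypeDescriptor:
    """2n, FN and what is known of chromosome morphology and CH blocks.

    ``chromosome_morphologies`` maps chromosome label to 'acrocentric',
    'metacentric' or 'submetacentric'; chromosomes whose morphology the
    source does not state are simply absent.  ``ch_blocks`` lists (chromosome,
    arm) pairs carrying large constitutive-heterochromatin blocks -- arms that
    take no painting signal but change FN.
    """

    taxon: str
    diploid_number: int
    fundamental_number: int
    chromosome_morphologies: dict[str, str] = field(default_factory=dict)
    ch_blocks: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        # rodent karyotypes run 2n >= 20; simulated toys may be smaller
        if self.diploid_number % 2 or self.diploid_number < 4:
            raise PaintingError(f"{self.taxon}: implausible 2n {self.diploid_number}")
        for m in self.chromosome_morphologies.values():
            if m not in ("acrocentric", "metacentric", "submetacentric"):
                raise PaintingError(f"{self.taxon}: bad morphology {m!r}")
        for chrom, arm in self.ch_blocks:
            if chrom not in self.chromosome_morphologies:
                raise PaintingError(
                    f"{self.taxon}: CH block on {chrom}{arm} but no morphology for {chrom}"
                )

    @property
    def n_autosome_pairs(self) -> int:
        return (self.diploid_number - 2) // 2

    @property
    def biarmed_autosome_pairs(self) -> int:
        """Bi-armed autosome pairs implied by FN (arms minus chromosomes)."""
        autosomes = self.diploid_number - 2
        return (self.fundamental_number - autosomes) // 2


@dataclass
class HomologyTable:
    """taxon x probe -> signal loci, with optional per-taxon descriptors.

    ``probes`` defaults to the 24 HME probes; simulated tables may carry
    their own probe set.
    """

    taxa: tuple[str, ...]
    entries: dict[tuple[str, str], list[SignalLocus]]
    descriptors: dict[str, KaryotypeDescriptor] = field(default_factory=dict)
    checksums: dict[str, int] = field(default_factory=dict)
    probes: tuple[str, ...] = PROBES

    def signals(self, taxon: str, probe: str) -> list[SignalLocus]:
        self._check_taxon(taxon)
        if probe not in self.probes:
            raise KeyError(f"unknown probe {probe!r}")
        return self.entries[(taxon, probe)]

    def _check_taxon(self, taxon: str) -> None:
        if taxon not in self.taxa:
            raise KeyError(f"unknown taxon {taxon!r}; have {', '.join(self.taxa)}")

    def validate(self) -> None:
        missing = [
            (t, p) for t in self.taxa for p in self.probes
            if not self.entries.get((t, p))
        ]
        if missing:
            gaps = ", ".join(f"{t}/{p}" for t, p in missing[:8])
            raise PaintingError(f"missing or empty cells: {gaps}"
                                + (" ..." if len(missing) > 8 else ""))
        for taxon, want in self.checksums.items():
            got = total_signals(self, taxon)
            if got != want:
                raise IntegrityError(
                    f"{taxon}: {got} signals, checksum row says {want}"
                )

    def chromosomes(self, taxon: str, *, autosomal_probes_only: bool = False) -> set[str]:
        """Target chromosome labels receiving at least one signal."""
        self._check_taxon(taxon)
        out: set[str] = set()
        for probe in self.probes:
            if autosomal_probes_only and probe == "X":
                continue
            out.update(loc.chromosome for loc in self.entries[(taxon, probe)])
        return out


def total_signals(table: HomologyTable, taxon: str) -> int:
    """Painted-segment total for one taxon (the printed "signs" count)."""
    table._check_taxon(taxon)
    return sum(
        loc.n_segments for p in table.probes for loc in table.entries[(taxon, p)]
    )


def conserved_synteny_probes(table: HomologyTable, taxon: str) -> set[str]:
    """Probes whose block remains on a single target chromosome.

    A probe shows conserved synteny when all of its signals in ``taxon`` fall
    on one chromosome (a block split within one chromosome -- e.g. painted on
    both arms -- is still conserved); the X probe counts among the 24.
    """
    table._check_taxon(taxon)
    return {
        p for p in table.probes
        if len({loc.chromosome for loc in table.entries[(taxon, p)]}) == 1
    }


def association_chromosomes(table: HomologyTable, taxon: str) -> set[str]:
    """Target chromosomes carrying syntenic blocks of >= 2 autosomal probes.

    The X probe is excluded; a composite probe counts once however many of
    its signals share the chromosome.
    """
    table._check_taxon(taxon)
    probes_on: dict[str, set[str]] = {}
    for p in table.probes:
        if p == "X":
            continue
        for loc in table.entries[(taxon, p)]:
            probes_on.setdefault(loc.chromosome, set()).add(p)
    return {c for c, ps in probes_on.items() if len(ps) >= 2}


# ---------------------------------------------------------------------------
# fixture + file IO

def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("karyophy") / "fixtures" / name))


def _hme_reference_entries() -> dict[tuple[str, str], list[SignalLocus]]:
    entries = {}
    for p in PROBES:
        chroms = p.strip("()").split(",") if p.startswith("(") else [p]
        entries[("HME", p)] = [SignalLocus(chromosome=c) for c in chroms]
    return entries


def _load_descriptors(path: Path) -> dict[str, KaryotypeDescriptor]:
    names = {"a": "acrocentric", "m": "metacentric", "sm": "submetacentric"}
    out = {}
    rows = [ln for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    header = rows[0].split("\t")
    for ln in rows[1:]:
        rec = dict(zip(header, ln.split("\t")))
        morphs = {}
        for item in filter(None, rec.get("morphologies", "").split(";")):
            chrom, cls = item.split(":")
            morphs[chrom] = names[cls]
        ch = []
        for item in filter(None, rec.get("ch_blocks", "").split(";")):
            ch.append((item[:-1], item[-1]))
        out[rec["taxon"]] = KaryotypeDescriptor(
            taxon=rec["taxon"],
            diploid_number=int(rec["diploid_number"]),
            fundamental_number=int(rec["fundamental_number"]),
            chromosome_morphologies=morphs,
            ch_blocks=ch,
        )
    return out


def load_homology_table(source: str | Path = "fixture:table2") -> HomologyTable:
    """Load and validate a homology table.

    ``source`` is ``"fixture:table2"`` for the packaged table, or a path to a
    TSV in the same dialect (cell-grammar columns per taxon, optional Total
    checksum row, '#' comments) or to a JSON file written by
    :func:`save_homology_table`.
    """
    if str(source) == "fixture:table2":
        path = _fixture_path("table2.tsv")
        descriptors = _load_descriptors(_fixture_path("descriptors.tsv"))
    else:
        path = Path(source)
        descriptors = {}
        if path.suffix == ".json":
            return _table_from_json(json.loads(path.read_text()))

    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    if header[0] != "probe":
        raise PaintingError(f"{path}: expected 'probe' header column")
    taxa = header[1:]
    entries: dict[tuple[str, str], list[SignalLocus]] = {}
    checksums: dict[str, int] = {}
    seen_probes = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        probe, row = cells[0], cells[1:]
        if probe == "Total":
            checksums = {t: int(v) for t, v in zip(taxa, row)}
            continue
        if probe not in PROBES:
            raise PaintingError(f"{path}: unknown probe row {probe!r}")
        seen_probes.append(probe)
        if len(row) != len(taxa):
            raise PaintingError(f"{path}: row {probe} has {len(row)} cells for {len(taxa)} taxa")
        for taxon, cell in zip(taxa, row):
            entries[(taxon, probe)] = parse_signal_cell(
                cell, where=f"(row {probe}, column {taxon})")
    missing_rows = set(PROBES) - set(seen_probes)
    if missing_rows:
        raise PaintingError(f"{path}: missing probe rows {sorted(missing_rows)}")

    all_taxa = tuple(taxa)
    if "HME" not in all_taxa:
        entries.update(_hme_reference_entries())
        all_taxa = ("HME", *all_taxa)
    table = HomologyTable(
        taxa=all_taxa, entries=entries, descriptors=descriptors, checksums=checksums
    )
    table.validate()
    return table


def save_homology_table(table: HomologyTable, path: str | Path) -> None:
    """Write a table as round-trippable TSV (cell grammar) or JSON.

    The JSON mirror is a long-format record set with explicit per-locus
    fields (taxon, probe, signal_index, chromosome, arm, regions,
    two_segment), which is diff-friendly and loses nothing.
    """
    path = Path(path)
    if path.suffix == ".json":
        recs = []
        for (taxon, probe), loci in sorted(table.entries.items()):
            for i, loc in enumerate(loci):
                recs.append({
                    "taxon": taxon, "probe": probe, "signal_index": i,
                    "chromosome": loc.chromosome, "arm": loc.arm,
                    "regions": list(loc.regions), "two_segment": loc.two_segment,
                    "arm_printed": loc.arm_printed,
                })
        doc = {"taxa": list(table.taxa), "signals": recs,
               "checksums": table.checksums}
        path.write_text(json.dumps(doc, indent=1))
        return
    taxa = [t for t in table.taxa if t != "HME"]
    lines = ["probe\t" + "\t".join(taxa)]
    for p in table.probes:
        lines.append(p + "\t" + "\t".join(
            format_signal_cell(table.entries[(t, p)]) for t in taxa))
    if table.checksums:
        lines.append("Total\t" + "\t".join(str(table.checksums[t]) for t in taxa))
    path.write_text("\n".join(lines) + "\n")


def _table_from_json(doc: Mapping) -> HomologyTable:
    entries: dict[tuple[str, str], list[SignalLocus]] = {}
    for rec in doc["signals"]:
        key = (rec["taxon"], rec["probe"])
        entries.setdefault(key, []).append(SignalLocus(
            chromosome=rec["chromosome"], arm=rec["arm"],
            regions=tuple(rec["regions"]), two_segment=rec["two_segment"],
            arm_printed=rec.get("arm_printed", True),
        ))
    table = HomologyTable(
        taxa=tuple(doc["taxa"]), entries=entries,
        checksums={k: int(v) for k, v in doc.get("checksums", {}).items()},
    )
    table.validate()
    return table


def summary_table(table: HomologyTable) -> list[dict]:
    """Per-taxon summary: 2n, FN, signal total, conserved-synteny and
    association counts (the per-species counts the study reports)."""
    rows = []
    for t in table.taxa:
        d = table.descriptors.get(t)
        rows.append({
            "taxon": t,
            "2n": d.diploid_number if d else None,
            "FN": d.fundamental_number if d else None,
            "total_signals": total_signals(table, t),
            "conserved_synteny_probes": len(conserved_synteny_probes(table, t)),
            "association_chromosomes": len(association_chromosomes(table, t)),
        })
    return rows


def write_summary_tsv(table: HomologyTable, path: str | Path) -> None:
    rows = summary_table(table)
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join("" if r[c] is None else str(r[c]) for c in cols) + "\n")
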