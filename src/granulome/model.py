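"""Core domain types and text formats.

A genome is an ordered set of linear chromosomes, each a sequence of signed
synteny-block identifiers (the sign is the block's reading direction, i.e.
strand).  Blocks themselves live in *block tables*: one row per homologous
block, with a placement (scaffold, 1-based inclusive gene-index span, strand)
and a gene count for each genome it is placed in, plus a "colour" label in
1..21 identifying the ancestral core-eudicot chromosome the block descends
from.

Two text formats are supported:

* GRIMM-style genome files: a ``>name`` header followed by one line per
  chromosome of whitespace-separated signed integers terminated by ``$``.
* Tab-separated block tables with header
  ``block_id  colour  <g>_scaffold  <g>_start  <g>_end  <g>_strand  <g>_genes``
  repeated for every placed genome ``<g>`` (and an optional trailing
  ``polarity_determinate`` column).  ``.`` marks a missing optional field.

Coordinates are ordinal gene positions along a scaffold, not base pairs:
every size, gap and threshold in this package is counted in genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "GranulomeError",
    "FormatError",
    "DataError",
    "ContentMismatchError",
    "UndefinedValueError",
    "SignedBlockGenome",
    "Placement",
    "SyntenyBlockRecord",
    "BlockTable",
    "read_genome",
    "write_genome",
    "genome_from_text",
    "genome_to_text",
    "read_block_table",
    "write_block_table",
    "genome_from_table",
]

MAX_COLOUR = 21


class GranulomeError(Exception):
    """Base class for package errors."""


class FormatError(GranulomeError):
    """A text input does not conform to the expected format."""


class DataError(GranulomeError):
    """Structurally valid input that violates a domain invariant."""


class ContentMismatchError(GranulomeError):
    """Two genomes do not carry the same set of blocks."""

    def __init__(self, only_a: Iterable[int], only_b: Iterable[int]):
        self.only_a = sorted(only_a)
        self.only_b = sorted(only_b)
        super().__init__(
            f"genomes differ in block content: "
            f"private to first={self.only_a}, private to second={self.only_b}"
        )


class UndefinedValueError(GranulomeError):
    """A statistic is undefined for the given input (e.g. r = 2d/b at b = 0)."""


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedBlockGenome:
    """A genome as ordered linear chromosomes of signed block identifiers.

    Invariants: at least one chromosome, every chromosome non-empty, and each
    unsigned block identifier occurs at most once in the whole genome.
    Chromosomes are linear; circular chromosomes are rejected wherever they
    could arise (plant nuclear genomes are linear).
    """

    name: str
    chromosomes: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        chroms = tuple(tuple(int(x) for x in c) for c in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if len(chroms) < 1:
            raise DataError(f"genome {self.name!r} has no chromosomes")
        seen: set[int] = set()
        for c in chroms:
            if len(c) == 0:
                raise DataError(f"genome {self.name!r} has an empty chromosome")
            for x in c:
                if x == 0:
                    raise DataError("block identifier 0 is not allowed")
                if abs(x) in seen:
                    raise DataError(f"duplicate block {abs(x)} in genome {self.name!r}")
                seen.add(abs(x))

    def blocks(self) -> frozenset[int]:
        """Unsigned block content."""
        return frozenset(abs(x) for c in self.chromosomes for x in c)

    @property
    def n_blocks(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def chromosome_index(self) -> dict[int, int]:
        """Map unsigned block -> 0-based index of its chromosome."""
        return {
            abs(x): i for i, c in enumerate(self.chromosomes) for x in c
        }

    def canonical(self, name: str | None = None) -> "SignedBlockGenome":
        """Orientation- and order-normalised copy.

        Each chromosome is flipped, if needed, so that of the two equivalent
        readings the lexicographically smaller tuple is kept; chromosomes are
        then sorted.  Two genomes that differ only by chromosome order or
        whole-chromosome flips canonicalise identically.
        """
        chroms = []
        for c in self.chromosomes:
            rev = tuple(-x for x in reversed(c))
            chroms.append(min(c, rev))
        chroms.sort()
        return SignedBlockGenome(name if name is not None else self.name, tuple(chroms))

    def rename(self, name: str) -> "SignedBlockGenome":
        return replace(self, name=name)


_HEADER_RE = re.compile(r"^>\s*(\S.*?)\s*$")


def genome_from_text(text: str) -> SignedBlockGenome:
    """Parse one GRIMM-style genome from a string."""
    name = None
    chroms: list[tuple[int, ...]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _HEADER_RE.match(line)
        if m:
            if name is not None:
                break  # only the first genome of a multi-genome file
            name = m.group(1)
            continue
        if name is None:
            raise FormatError(f"line {lineno}: chromosome data before '>' header")
        if line.endswith("@"):
            raise FormatError(
                f"line {lineno}: circular chromosome ('@') not supported"
            )
        if not line.endswith("$"):
            raise FormatError(f"line {lineno}: chromosome line must end with '$'")
        body = line[:-1].split()
        if not body:
            raise FormatError(f"line {lineno}: empty chromosome")
        try:
            chrom = tuple(int(tok) for tok in body)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer block token") from exc
        chroms.append(chrom)
    if name is None:
        raise FormatError("no '>' genome header found")
    try:
        return SignedBlockGenome(name, tuple(chroms))
    except DataError as exc:
        raise FormatError(str(exc)) from exc


def genome_to_text(g: SignedBlockGenome) -> str:
    lines = [f">{g.name}"]
    for c in g.chromosomes:
        lines.append(" ".join(str(x) for x in c) + " $")
    return "\n".join(lines) + "\n"


def read_genome(path: str | Path) -> SignedBlockGenome:
    """Read a GRIMM-style genome file (first genome if several)."""
    return genome_from_text(Path(path).read_text())


def write_genome(g: SignedBlockGenome, path: str | Path) -> None:
    Path(path).write_text(genome_to_text(g))


# ---------------------------------------------------------------------------
# block tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """Where a block sits in one genome: scaffold, gene-index span, strand."""

    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"unknown strand symbol {self.strand!r}")
        if self.start > self.end:
            raise FormatError(
                f"start {self.start} > end {self.end} on scaffold {self.scaffold!r}"
            )
        if self.start < 1:
            raise FormatError("gene indices are 1-based")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class SyntenyBlockRecord:
    """One homologous block with a placement per genome.

    ``genes`` counts the genes actually attributed to the block in each
    genome; fractionation means this may be smaller than the spanned
    interval.  ``polarity_determinate`` is False when the record was built by
    merging parts whose relative orientations disagree between genomes, so
    the block's sign is unresolved until the polarity search fixes it.
    """

    block_id: str
    colour: int
    placements: dict[str, Placement]
    genes: dict[str, int]
    polarity_determinate: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.colour <= MAX_COLOUR:
            raise DataError(
                f"block {self.block_id!r}: colour {self.colour} outside 1..{MAX_COLOUR}"
            )
        if set(self.placements) != set(self.genes):
            raise DataError(f"block {self.block_id!r}: placements/genes genome mismatch")
        for g, p in self.placements.items():
            n = self.genes[g]
            if n < 0:
                raise DataError(f"block {self.block_id!r}: negative gene count in {g}")
            if n > p.span:
                raise DataError(
                    f"block {self.block_id!r}: {n} genes exceed span {p.span} in {g}"
                )


@dataclass
class BlockTable:
    """A list of block records all placed in the same 2 or 3 genomes."""

    records: list[SyntenyBlockRecord]
    genome_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.genome_names = tuple(self.genome_names)
        names = set(self.genome_names)
        seen: set[str] = set()
        for r in self.records:
            if set(r.placements) != names:
                raise DataError(
                    f"block {r.block_id!r} places {sorted(r.placements)}, "
                    f"table places {sorted(names)}"
                )
            if r.block_id in seen:
                raise DataError(f"duplicate block_id {r.block_id!r}")
            seen.add(r.block_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SyntenyBlockRecord]:
        return iter(self.records)

    def block_index(self) -> dict[str, int]:
        """Stable ``block_id -> integer`` map (row order), shared by all
        genomes extracted from this table."""
        return {r.block_id: i + 1 for i, r in enumerate(self.records)}

    def total_genes(self, genome: str) -> int:
        return sum(r.genes[genome] for r in self.records)

    def subset(self, keep) -> "BlockTable":
        return BlockTable([r for r in self.records if keep(r)], self.genome_names)


def _table_columns(genome_names: Sequence[str]) -> list[str]:
    cols = ["block_id", "colour"]
    for g in genome_names:
        cols += [f"{g}_scaffold", f"{g}_start", f"{g}_end", f"{g}_strand", f"{g}_genes"]
    return cols + ["polarity_determinate"]


def write_block_table(t: BlockTable, path: str | Path) -> None:
    rows = []
    for r in t.records:
        row: dict[str, object] = {"block_id": r.block_id, "colour": r.colour}
        for g in t.genome_names:
            p = r.placements[g]
            row[f"{g}_scaffold"] = p.scaffold
            row[f"{g}_start"] = p.start
            row[f"{g}_end"] = p.end
            row[f"{g}_strand"] = p.strand
            row[f"{g}_genes"] = r.genes[g]
        row["polarity_determinate"] = int(r.polarity_determinate)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_table_columns(t.genome_names))
    df.to_csv(path, sep="\t", index=False)


def read_block_table(path: str | Path) -> BlockTable:
    """Read a block-table TSV; genome names are recovered from the header."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if cols[:2] != ["block_id", "colour"]:
        raise FormatError("block table must start with columns block_id, colour")
    genome_names = []
    for c in cols[2:]:
        if c.endswith("_scaffold"):
            genome_names.append(c[: -len("_scaffold")])
    if not genome_names:
        raise FormatError("no per-genome column groups found in header")
    records = []
    for _, row in df.iterrows():
        placements: dict[str, Placement] = {}
        genes: dict[str, int] = {}
        for g in genome_names:
            try:
                placements[g] = Placement(
                    scaffold=row[f"{g}_scaffold"],
                    start=int(row[f"{g}_start"]),
                    end=int(row[f"{g}_end"]),
                    strand=row[f"{g}_strand"],
                )
                genes[g] = int(row[f"{g}_genes"])
            except (KeyError, ValueError) as exc:
                raise FormatError(
                    f"block {row['block_id']!r}: bad fields for genome {g!r}"
                ) from exc
        pol = row.get("polarity_determinate", "1")
        try:
            rec = SyntenyBlockRecord(
                block_id=row["block_id"],
                colour=int(row["colour"]),
                placements=placements,
                genes=genes,
                polarity_determinate=pol not in ("0", "False", "false"),
            )
        except DataError as exc:
            raise FormatError(str(exc)) from exc
        records.append(rec)
    try:
        return BlockTable(records, tuple(genome_names))
    except DataError as exc:
        raise FormatError(str(exc)) from exc


def genome_from_table(
    t: BlockTable,
    genome_name: str,
    sign_by: str = "strand",
    block_ids: Mapping[str, int] | None = None,
) -> SignedBlockGenome:
    """Order the table's blocks into a signed genome for one of its genomes.

    Blocks on each scaffold are ordered by start index and signed by strand;
    scaffolds become chromosomes, ordered lexicographically by scaffold id.
    Integer block identifiers come from :meth:`BlockTable.block_index` (or an
    explicit ``block_ids`` map) so that the three genomes extracted from one
    table are directly comparable.
    """
    if sign_by != "strand":
        raise ValueError("only sign_by='strand' is supported")
    if genome_name not in t.genome_names:
        raise ValueError(f"genome {genome_name!r} not placed in table")
    ids = dict(block_ids) if block_ids is not None else t.block_index()
    by_scaffold: dict[str, list[SyntenyBlockRecord]] = {}
    for r in t.records:
        by_scaffold.setdefault(r.placements[genome_name].scaffold, []).append(r)
    chroms = []
    for scaf in sorted(by_scaffold):
        recs = sorted(by_scaffold[scaf], key=lambda r: r.placements[genome_name].start)
        prev = None
        chrom = []
        for r in recs:
            p = r.placements[genome_name]
            if prev is not None and p.start <= prev.placements[genome_name].end:
                raise DataError(
                    f"overlapping spans on scaffold {scaf!r} of {genome_name!r}: "
                    f"{prev.block_id!r} and {r.block_id!r}"
                )
            chrom.append(ids[r.block_id] if p.strand == "+" else -ids[r.block_id])
            prev = r
        chroms.append(tuple(chrom))
    if not chroms:
        raise DataError(f"no blocks placed in {genome_name!r}")
    return SignedBlockGenome(genome_name, tuple(chroms))
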