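"""Secondary-structure-annotated alignments: reading, classification, partitioning.

An rDNA consensus alignment carries a dot-bracket mask: matching parentheses
mark the two sides of a helix (stem), dots mark unpaired (loop) columns.
Regions whose structure is not conserved across taxa (regions of ambiguous
alignment, RAA — including expansion/contraction and slipped-strand
subclasses) are annotated as column spans and excluded from the
structure-consensus partitions; they are rescued separately by the
:mod:`structsignal.raa` pipeline.

Coordinates are 0-based half-open internally; all written reports are 1-based
inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .alignment import GAP, IUPAC, Alignment, normalize_seq

log = logging.getLogger(__name__)

MASK_CHARS = set("().")
STRUCTURE_RECORD_ID = "#structure"


class ColumnClass(str, Enum):
    STEM = "STEM"
    LOOP = "LOOP"
    RAA = "RAA"


@dataclass
class RaaSpan:
    """One annotated ambiguous region: [start, end) in master coordinates."""

    block_id: str
    start: int
    end: int
    subclass: str = "RAA"  # REC / RAA / RSC recorded but treated uniformly

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span {self.block_id}: [{self.start}, {self.end})")


class StructureError(ValueError):
    pass


class FormatError(ValueError):
    pass


@dataclass
class StructuredAlignment:
    """Alignment plus per-column class and stem pairing map."""

    alignment: Alignment
    mask: str
    raa_spans: list[RaaSpan] = field(default_factory=list)
    pairing: dict[int, int] = field(default_factory=dict)
    orphan_paired: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        L = self.alignment.n_columns
        if len(self.mask) != L:
            raise FormatError(
                f"mask length {len(self.mask)} != alignment length {L}"
            )
        bad = set(self.mask) - MASK_CHARS
        if bad:
            raise FormatError(f"invalid mask characters: {sorted(bad)}")
        if not self.pairing and not self.orphan_paired:
            self.pairing, self.orphan_paired = match_brackets(self.mask)
        self._check_spans()
        self._check_pairing()

    def _check_spans(self) -> None:
        L = self.alignment.n_columns
        spans = sorted(self.raa_spans, key=lambda s: s.start)
        prev_end = 0
        seen = set()
        for s in spans:
            if s.block_id in seen:
                raise FormatError(f"duplicate RAA block id {s.block_id}")
            seen.add(s.block_id)
            if s.start < prev_end:
                raise FormatError(f"overlapping RAA spans at block {s.block_id}")
            if s.end > L:
                raise FormatError(f"RAA span {s.block_id} exceeds alignment length")
            prev_end = s.end
        self.raa_spans = spans

    def _check_pairing(self) -> None:
        for i, j in self.pairing.items():
            if i == j:
                raise StructureError(f"self-paired column {i}")
            if self.pairing.get(j) != i:
                raise StructureError(f"pairing not symmetric at column {i}")

    # -- column classification -------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return self.alignment.taxa

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns

    def column_classes(self) -> list[ColumnClass]:
        classes = []
        in_raa = set()
        for s in self.raa_spans:
            in_raa.update(range(s.start, s.end))
        for j in range(self.n_columns):
            if j in in_raa:
                classes.append(ColumnClass.RAA)
            elif self.mask[j] in "()":
                classes.append(ColumnClass.STEM)
            else:
                classes.append(ColumnClass.LOOP)
        return classes

    def columns_of_class(self, cls: ColumnClass | str) -> list[int]:
        want = _parse_class(cls)
        return [j for j, c in enumerate(self.column_classes()) if c in want]

    def n_paired(self) -> int:
        """Columns marked as pairing, orphans included (an odd count is legal:
        a helix side may be missing when one strand was not sequenced)."""
        return sum(1 for c in self.mask if c in "()")


def _parse_class(cls: ColumnClass | str) -> set[ColumnClass]:
    if isinstance(cls, ColumnClass):
        return {cls}
    parts = cls.upper().replace(" ", "").split("+")
    try:
        return {ColumnClass(p) for p in parts}
    except ValueError as e:
        raise ValueError(f"unknown column class {cls!r}") from e


def match_brackets(mask: str) -> tuple[dict[int, int], set[int]]:
    """Stack-match parentheses in a dot-bracket mask.

    Returns (pairing, orphans).  Unmatched brackets are reported as orphan
    paired columns with a warning — they arise when part of a helix falls
    outside the sequenced region.
    """
    stack: list[int] = []
    pairing: dict[int, int] = {}
    orphans: set[int] = set()
    for j, c in enumerate(mask):
        if c == "(":
            stack.append(j)
        elif c == ")":
            if stack:
                i = stack.pop()
                pairing[i] = j
                pairing[j] = i
            else:
                orphans.add(j)
    orphans.update(stack)
    if orphans:
        log.warning(
            "%d bracket column(s) lack a partner; recorded as orphan paired columns",
            len(orphans),
        )
    return pairing, orphans


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_raa_annotation(path: str | Path) -> list[RaaSpan]:
    """Read the sidecar RAA annotation: TSV of block id, start, end
    (0-based half-open), optional subclass (REC/RAA/RSC)."""
    spans = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"bad RAA annotation line: {line!r}")
        sub = parts[3] if len(parts) > 3 else "RAA"
        spans.append(RaaSpan(parts[0], int(parts[1]), int(parts[2]), sub))
    return spans


def _spans_from_lowercase(records: list[tuple[str, str]]) -> list[RaaSpan]:
    """Alternative RAA convention: ambiguous columns written lowercase in the
    sequence rows.  A column is ambiguous when every non-gap residue in it is
    lowercase; maximal runs become blocks."""
    L = len(records[0][1])
    is_raa = []
    for j in range(L):
        col = [r[1][j] for r in records if r[1][j] != GAP]
        is_raa.append(bool(col) and all(c.islower() for c in col))
    spans = []
    start = None
    for j, flag in enumerate(is_raa + [False]):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            spans.append(RaaSpan(f"RAA{len(spans) + 1}", start, j))
            start = None
    return spans


def read_structured_fasta(
    path: str | Path,
    raa_annotation: Optional[str | Path] = None,
) -> StructuredAlignment:
    """Read a FASTA alignment carrying a dot-bracket structure line.

    The mask is the record with id ``#structure``, or failing that a trailing
    record whose sequence is entirely over ``(``, ``)``, ``.``.  RAA spans come
    from the sidecar annotation when given, otherwise from lowercase sequence
    runs (auto-detected), otherwise none.
    """
    raw = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise FormatError(f"no records in {path}")
    mask = None
    records = []
    for rid, seq in raw:
        if rid == STRUCTURE_RECORD_ID or (
            mask is None and set(seq) <= MASK_CHARS and seq
        ):
            if set(seq) <= MASK_CHARS:
                mask = seq
                continue
        records.append((rid, seq))
    if mask is None:
        raise FormatError(f"no structure mask record found in {path}")
    L = len(mask)
    for rid, seq in records:
        if len(seq) != L:
            raise FormatError(
                f"record {rid!r}: length {len(seq)} != mask length {L}"
            )
    if raa_annotation is not None:
        spans = read_raa_annotation(raa_annotation)
    else:
        spans = _spans_from_lowercase(records)
        if spans:
            log.info("inferred %d RAA block(s) from lowercase convention", len(spans))
    aln = Alignment([r[0] for r in records], [r[1] for r in records])
    return StructuredAlignment(aln, mask, spans)


# ---------------------------------------------------------------------------
# partition extraction & site patterns
# ---------------------------------------------------------------------------

def extract_partition(
    saln: StructuredAlignment, cls: ColumnClass | str
) -> tuple[Alignment, list[int]]:
    """Extract the columns of one class (or a '+'-union such as STEM+LOOP).

    Returns the sub-alignment and the provenance map: provenance[k] is the
    master coordinate of sub-column k.  Column and taxa order are preserved;
    an empty class yields an empty alignment.
    """
    idx = saln.columns_of_class(cls)
    return saln.alignment.take_columns(idx), idx


@dataclass
class PartitionCounts:
    n_columns: int
    n_constant: int
    n_variable_uninformative: int
    n_parsimony_informative: int
    n_paired: int = 0
    n_unpaired: int = 0


def count_site_patterns(
    aln: Alignment, mask: Optional[str] = None, strict_constant: bool = False
) -> PartitionCounts:
    """Classify every column as constant / variable-uninformative /
    parsimony-informative.

    Gaps and ambiguity codes are not counted as states.  By default a column
    with a single real state plus gaps is constant; ``strict_constant``
    additionally requires the column to be gap-free.  A parsimony-informative
    column has at least two states each carried by at least two taxa.
    """
    if aln.n_taxa == 0:
        raise ValueError("alignment has no taxa")
    n_const = n_unin = n_inf = 0
    for col in aln.columns():
        states = [c for c in col if c in "ACGT"]
        counts: dict[str, int] = {}
        for c in states:
            counts[c] = counts.get(c, 0) + 1
        distinct = len(counts)
        if distinct <= 1:
            if strict_constant and (GAP in col or len(states) < len(col)):
                n_unin += 1
            else:
                n_const += 1
        elif sum(1 for v in counts.values() if v >= 2) >= 2:
            n_inf += 1
        else:
            n_unin += 1
    n_paired = sum(1 for c in mask if c in "()") if mask is not None else 0
    return PartitionCounts(
        n_columns=aln.n_columns,
        n_constant=n_const,
        n_variable_uninformative=n_unin,
        n_parsimony_informative=n_inf,
        n_paired=n_paired,
        n_unpaired=aln.n_columns - n_paired if mask is not None else 0,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _ranges_1based(idx: list[int]) -> str:
    """Compress sorted indices into 1-based inclusive 'a-b' ranges."""
    if not idx:
        return ""
    runs = []
    start = prev = idx[0]
    for j in idx[1:]:
        if j == prev + 1:
            prev = j
        else:
            runs.append((start, prev))
            start = prev = j
    runs.append((start, prev))
    return ", ".join(f"{a + 1}-{b + 1}" for a, b in runs)


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Relaxed PHYLIP: name, whitespace, sequence on one line."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.n_columns}\n")
        width = max((len(t) for t in aln.taxa), default=0) + 2
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f"{t:<{width}}{r}\n")


def read_phylip(path: str | Path) -> Alignment:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    n, L = int(header[0]), int(header[1])
    taxa, rows = [], []
    for ln in lines[1 : 1 + n]:
        name, seq = ln.split(None, 1)
        seq = seq.replace(" ", "")
        if len(seq) != L:
            raise FormatError(f"record {name!r}: length {len(seq)} != {L}")
        taxa.append(name)
        rows.append(seq)
    return Alignment(taxa, rows)


def write_partition_files(saln: StructuredAlignment, outdir: str | Path) -> dict[str, Path]:
    """Write one relaxed-PHYLIP file per partition, a partition-definition
    file (1-based inclusive ranges) and a structure-line file mirroring the
    mask (orphan paired columns demoted to '.' with a warning).

    Returns a name -> path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    part_lines = []
    for cls in (ColumnClass.STEM, ColumnClass.LOOP, ColumnClass.RAA):
        sub, prov = extract_partition(saln, cls)
        if sub.n_columns:
            p = outdir / f"{cls.value.lower()}.phy"
            write_phylip(sub, p)
            written[cls.value.lower()] = p
        part_lines.append(f"{cls.value} = {_ranges_1based(prov)}")
    pfile = outdir / "partitions.txt"
    pfile.write_text("\n".join(part_lines) + "\n")
    written["partitions"] = pfile
    mask_out = list(saln.mask)
    if saln.orphan_paired:
        log.warning(
            "structure file: %d orphan paired column(s) written as unpaired",
            len(saln.orphan_paired),
        )
        for j in saln.orphan_paired:
            mask_out[j] = "."
    sfile = outdir / "structure.txt"
    sfile.write_text("".join(mask_out) + "\n")
    written["structure"] = sfile
    ffile = outdir / "alignment.fasta"
    write_structured_fasta(saln, ffile)
    written["fasta"] = ffile
    return written


def write_structured_fasta(saln: StructuredAlignment, path: str | Path) -> None:
    """FASTA with a '#structure' mask record; round-trips with
    :func:`read_structured_fasta` (RAA spans go in a sidecar)."""
    with open(path, "w") as fh:
        fh.write(f">{STRUCTURE_RECORD_ID}\n{saln.mask}\n")
        for t, r in zip(saln.alignment.taxa, saln.alignment.rows):
            fh.write(f">{t}\n{r}\n")


def write_raa_annotation(spans: list[RaaSpan], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#block_id\tstart\tend\tsubclass\n")
        for s in spans:
            fh.write(f"{s.block_id}\t{s.start}\t{s.end}\t{s.subclass}\n")
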