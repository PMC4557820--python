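"""Lightweight aligned-matrix container shared by all pipeline stages.

Sequences are stored as plain strings over the IUPAC nucleotide alphabet plus
the gap character ``-``.  ``U`` is folded to ``T`` on construction so RNA and
DNA input behave identically downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

GAP = "-"
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC ambiguity codes -> set of compatible bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

VALID_CHARS = set(IUPAC) | {GAP}


def normalize_seq(seq: str) -> str:
    """Uppercase, fold U->T, validate against IUPAC + gap."""
    s = seq.upper().replace("U", "T").replace("?", "N")
    bad = set(s) - VALID_CHARS
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return s


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon label(s): {dup}")
        self.rows = [normalize_seq(r) for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def columns(self) -> Iterable[str]:
        for j in range(self.n_columns):
            yield self.column(j)

    def take_columns(self, idx: Sequence[int]) -> "Alignment":
        idx = list(idx)
        return Alignment(list(self.taxa), ["".join(r[j] for j in idx) for r in self.rows])

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def to_array(self) -> np.ndarray:
        """(n_taxa, n_columns) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and self.rows == other.rows
        )
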