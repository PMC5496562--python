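"""Species-labelled aligned sequence sets and terminal-gap trimming.

The central container is :class:`AlignedSet`: one pre-aligned sequence per
species, all of identical length.  Alignment itself (ClustalW, MAFFT, MEGA,
...) is an upstream step performed with external tools; this module only
consumes its multi-FASTA output.

Positions are 1-based throughout the package and refer to columns of the
*trimmed* common region — the blunt-ended block covered by every sequence —
which serves as the coordinate frame for SNP barcode positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import NoCommonRegionError, NotAlignedError

GAP = "-"
NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class AlignedSet:
    """A rectangular alignment of one sequence per species.

    Parameters
    ----------
    labels : tuple of str
        Unique, non-empty species identifiers, in input order.
    rows : tuple of str
        Aligned sequences over ``{A, C, G, T, N, -}`` (other IUPAC ambiguity
        letters are tolerated and treated like ``N`` downstream).  All rows
        share one length.
    origin_offset : int
        Number of leading alignment columns removed by trimming; 0 for an
        untrimmed set.  Provenance only — positions are always numbered
        1..M on the current matrix.
    """

    labels: tuple[str, ...]
    rows: tuple[str, ...]
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an AlignedSet needs at least 2 species")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise NotAlignedError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise ValueError("sequences are empty")
        if any(not lab for lab in self.labels):
            raise ValueError("empty species label")
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise ValueError(f"duplicate species labels: {sorted(dupes)}")

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        """Alignment length M (number of columns)."""
        return len(self.rows[0])

    @cached_property
    def matrix(self) -> np.ndarray:
        """The alignment as an (N, M) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def column(self, position: int) -> str:
        """Symbols in 1-based column `position`, in row order."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return "".join(r[position - 1] for r in self.rows)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_aligned_fasta(path: str | Path) -> AlignedSet:
    """Read a species-labelled aligned multi-FASTA.

    The species label is the header up to the first whitespace.  Symbols are
    upper-cased and RNA ``U`` is mapped to ``T``.

    Raises
    ------
    NotAlignedError
        If records differ in length.
    ValueError
        On duplicate labels or an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    labels = tuple(rec.id for rec in records)
    rows = tuple(_normalize(str(rec.seq)) for rec in records)
    return AlignedSet(labels=labels, rows=rows)


def write_aligned_fasta(a: AlignedSet, path: str | Path) -> None:
    """Write an AlignedSet as multi-FASTA (60-column wrap).

    Round-trips through :func:`read_aligned_fasta` on labels and matrix.
    """
    records = [
        SeqRecord(Seq(row), id=label, description="")
        for label, row in zip(a.labels, a.rows)
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def _span(row: str) -> tuple[int, int]:
    """0-based [first, last] non-gap index of a row; raises if all-gap."""
    stripped = row.strip(GAP)
    if not stripped:
        raise NoCommonRegionError("a sequence is entirely gaps")
    first = len(row) - len(row.lstrip(GAP))
    last = len(row.rstrip(GAP)) - 1
    return first, last


def trim_common_region(a: AlignedSet) -> AlignedSet:
    """Trim to the blunt-ended common region covered by ALL sequences.

    Protruding 5'/3' ends (columns where any sequence has a terminal gap)
    are removed; the remaining block is renumbered 1..M'.  Internal gaps are
    untouched — they are excluded from candidacy downstream, not trimmed.
    Idempotent.

    Raises
    ------
    NoCommonRegionError
        If no column is covered by every sequence.
    """
    spans = [_span(r) for r in a.rows]
    start = max(s for s, _ in spans)
    end = min(e for _, e in spans)
    if start > end:
        raise NoCommonRegionError(
            "no common region: sequences do not all overlap"
        )
    if start == 0 and end == a.length - 1:
        return a
    rows = tuple(r[start : end + 1] for r in a.rows)
    return AlignedSet(
        labels=a.labels, rows=rows, origin_offset=a.origin_offset + start
    )
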