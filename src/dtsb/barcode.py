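"""SNP barcode extraction, sorting/deduplication, matching and serialization.

A species' SNP barcode is the list of (level, position, nucleotide) triples
collected on its root-to-leaf path through the decision tree, where the
nucleotide is the species' OWN base at each decision position (not the
pivot).  Because the tree can reuse a position in nested subtrees, the raw
level-ordered barcode may repeat a position; the sorted barcode collapses
each position to a single entry and orders entries by position, giving the
compact species tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alignment import NUCLEOTIDES, AlignedSet
from .errors import AmbiguousBarcodeError, DTSBError
from .tree import DecisionNode

#: returned by match_barcode when no barcode fits the query
UNKNOWN = "unknown"


@dataclass(frozen=True)
class SNPBarcode:
    """Species-specific SNP tag.

    Attributes
    ----------
    species : str
    entries : tuple of (level, position, nucleotide)
        Root-to-leaf decision order; strictly increasing level; positions
        may repeat (with identical nucleotide).
    sorted_entries : tuple of (position, nucleotide)
        Ascending by position, duplicates collapsed to one entry.
    """

    species: str
    entries: tuple[tuple[int, int, str], ...]

    @cached_property
    def sorted_entries(self) -> tuple[tuple[int, str], ...]:
        by_position: dict[int, str] = {}
        for _level, position, base in self.entries:
            seen = by_position.get(position)
            if seen is not None and seen != base:
                raise DTSBError(
                    f"conflicting nucleotides {seen}/{base} at position "
                    f"{position} in barcode for {self.species}"
                )
            by_position.setdefault(position, base)
        return tuple(sorted(by_position.items()))

    @property
    def barcode_string(self) -> str:
        """Textual rendering, e.g. ``p12:A;p87:T``."""
        return ";".join(f"p{pos}:{base}" for pos, base in self.sorted_entries)


def sort_and_dedup(b: SNPBarcode) -> SNPBarcode:
    """Materialize the position-sorted, deduplicated view of a barcode.

    Idempotent; ``entries`` are untouched.  Raises :class:`DTSBError` if a
    repeated position carries conflicting nucleotides (impossible for a
    tree-derived barcode; signals corruption).
    """
    b.sorted_entries  # computes and caches; validates conflicts
    return b


def extract_barcodes(tree: DecisionNode, a: AlignedSet) -> list[SNPBarcode]:
    """One SNP barcode per species, in the alignment's species order.

    Each barcode records, per decision node on the species' root-to-leaf
    path, the level, the node's position and the species' own nucleotide
    there.

    Raises
    ------
    ValueError
        If a species of the alignment is missing from the tree.
    """
    paths: dict[str, tuple[tuple[int, int, str], ...]] = {}

    def descend(node: DecisionNode, prefix: tuple[tuple[int, int], ...]) -> None:
        if node.is_leaf:
            paths[node.species] = prefix
            return
        step = ((node.level, node.position),)
        descend(node.left, prefix + step)
        descend(node.right, prefix + step)

    descend(tree, ())
    missing = [lab for lab in a.labels if lab not in paths]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    barcodes = []
    for label, row in zip(a.labels, a.rows):
        entries = tuple(
            (level, position, row[position - 1]) for level, position in paths[label]
        )
        barcodes.append(sort_and_dedup(SNPBarcode(species=label, entries=entries)))
    return barcodes


def match_barcode(barcodes: Sequence[SNPBarcode], sequence: str) -> str:
    """Return the unique species whose sorted barcode matches the sequence.

    A barcode matches when the sequence carries the barcode's nucleotide at
    every one of its positions.  Returns :data:`UNKNOWN` when nothing
    matches.

    Raises
    ------
    AmbiguousBarcodeError
        If more than one barcode matches (impossible for barcodes derived
        from one tree; signals a corrupt barcode set).
    """
    sequence = sequence.upper()
    hits = [
        b.species
        for b in barcodes
        if all(sequence[pos - 1] == base for pos, base in b.sorted_entries)
    ]
    if not hits:
        return UNKNOWN
    if len(hits) > 1:
        raise AmbiguousBarcodeError(f"ambiguous barcode set: matches {hits}")
    return hits[0]


def barcode_table(barcodes: Sequence[SNPBarcode]) -> pd.DataFrame:
    """Barcodes as a tidy table, one row per species (input order)."""
    if not barcodes:
        raise ValueError("no barcodes to tabulate")
    return pd.DataFrame(
        {
            "species": [b.species for b in barcodes],
            "n_positions": [len(b.sorted_entries) for b in barcodes],
            "positions": [
                ",".join(str(pos) for pos, _ in b.sorted_entries) for b in barcodes
            ],
            "nucleotides": [
                "".join(base for _, base in b.sorted_entries) for b in barcodes
            ],
            "barcode_string": [b.barcode_string for b in barcodes],
        }
    )


def write_barcode_table(barcodes: Sequence[SNPBarcode], path: str | Path) -> None:
    """Write the barcode table as TSV."""
    barcode_table(barcodes).to_csv(path, sep="\t", index=False)


def read_barcode_table(path: str | Path) -> list[SNPBarcode]:
    """Reconstruct sorted barcodes from a TSV written by write_barcode_table.

    Level information is not stored in the table, so the reconstructed
    ``entries`` carry the sorted order with synthetic levels 1, 2, ...;
    ``sorted_entries`` round-trip exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"positions": str, "nucleotides": str})
    out = []
    for _, row in df.iterrows():
        if int(row["n_positions"]) == 0:
            out.append(SNPBarcode(species=row["species"], entries=()))
            continue
        positions = [int(x) for x in str(row["positions"]).split(",")]
        bases = list(str(row["nucleotides"]))
        entries = tuple(
            (i + 1, pos, base) for i, (pos, base) in enumerate(zip(positions, bases))
        )
        out.append(sort_and_dedup(SNPBarcode(species=row["species"], entries=entries)))
    return out


def barcodes_to_json(barcodes: Sequence[SNPBarcode], path: str | Path) -> None:
    """JSON export mirroring the barcode fields."""
    doc = [
        {
            "species": b.species,
            "entries": [list(e) for e in b.entries],
            "sorted_entries": [list(e) for e in b.sorted_entries],
            "barcode_string": b.barcode_string,
        }
        for b in barcodes
    ]
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
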