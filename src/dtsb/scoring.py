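"""The mid/diff/weight position score used to pick decision nodes.

For a node holding ``n`` sequences, a column's score is

    score_p = (mid_p - diff_p) / mid_p + weight_p

with ``mid_p = n / 2``, ``diff_p = min_i |mid_p - f_i^p|`` over the four
canonical bases, and ``weight_p`` a bonus keyed to the number of nucleotide
types observed at the column (0, 1, 0.66, 0.33 for 1, 2, 3, 4 types; the
printed decimal constants, not 2/3 and 1/3).  The balance term is 0 for an
invariant column and 1 for a perfectly even cut, so 0 <= score <= 2 with the
maximum attained by a balanced biallelic site.

All arithmetic is exact (:class:`fractions.Fraction`) so that score ties are
detected exactly and tie-breaking is platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .alignment import NUCLEOTIDES

#: weight_p by number of nucleotide types present at the column
TYPE_WEIGHTS: dict[int, Fraction] = {
    1: Fraction(0),
    2: Fraction(1),
    3: Fraction(66, 100),
    4: Fraction(33, 100),
}


def type_weight(n_types: int) -> Fraction:
    """Weight bonus for a column showing `n_types` distinct nucleotides."""
    if n_types not in TYPE_WEIGHTS:
        raise ValueError(f"number of nucleotide types must be 1..4, got {n_types}")
    return TYPE_WEIGHTS[n_types]


@dataclass(frozen=True)
class ScoreBreakdown:
    """Score of one column with its intermediate quantities.

    ``pivot`` is the base whose count is closest to ``mid`` (the argmin of
    the diff term, ties broken A < C < G < T): its carriers form the left
    branch when the column is chosen as a decision node.
    """

    position: int | None
    mid: Fraction
    diff: Fraction
    n_types: int
    weight: Fraction
    score: Fraction
    pivot: str

    def __float__(self) -> float:
        return float(self.score)


def position_score(
    counts: Sequence[int], node_size: int, position: int | None = None
) -> ScoreBreakdown:
    """Score one column of a node from its (f_A, f_C, f_G, f_T) counts.

    Parameters
    ----------
    counts : sequence of 4 ints
        Per-base counts at the column, in A, C, G, T order.
    node_size : int
        Number of sequences in the node; must equal ``sum(counts)``.
    position : int, optional
        1-based column index carried through for bookkeeping.

    Raises
    ------
    ValueError
        If the counts do not sum to ``node_size`` (gapped columns are not
        scorable) or ``node_size < 2``.
    """
    counts = [int(c) for c in counts]
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValueError("counts must be 4 non-negative integers (A, C, G, T)")
    if node_size < 2:
        raise ValueError("a node needs at least 2 sequences to score")
    if sum(counts) != node_size:
        raise ValueError(
            f"counts sum to {sum(counts)}, expected node size {node_size}"
        )
    mid = Fraction(node_size, 2)
    deviations = [abs(mid - c) for c in counts]
    diff = min(deviations)
    pivot = NUCLEOTIDES[deviations.index(diff)]  # alphabetical tie-break
    n_types = sum(1 for c in counts if c > 0)
    weight = type_weight(n_types)
    score = (mid - diff) / mid + weight
    return ScoreBreakdown(
        position=position,
        mid=mid,
        diff=diff,
        n_types=n_types,
        weight=weight,
        score=score,
        pivot=pivot,
    )
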