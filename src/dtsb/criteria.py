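"""Classical split criteria — information gain and Gini index.

These are the standard decision-tree impurity measures, provided as
alternative, pluggable node-scoring rules for comparison with the default
mid/diff/weight score.  The binary-target forms (``info``,
``expected_entropy``, ``information_gain``) follow the textbook closed
forms exactly; the multi-class entropy used when these criteria drive tree
construction (one class per species) is the usual generalization
``-sum_c P_c log2 P_c`` and is labelled as such.

Logarithms are base 2 throughout; entropies are in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class BinaryClassCounts:
    """Counts of positive- and negative-target samples at a node."""

    p: int
    n: int

    def __post_init__(self) -> None:
        if self.p < 0 or self.n < 0:
            raise ValueError("counts must be non-negative")
        if self.p + self.n < 1:
            raise ValueError("node must hold at least one sample")

    @property
    def total(self) -> int:
        return self.p + self.n


@dataclass(frozen=True)
class NodeClassDistribution:
    """Class membership probabilities P(i|e) at a tree node e.

    ``prior`` and ``class_sizes`` are optional bookkeeping (the prior pi_i
    and per-class record counts N_i(e), N_i); only ``class_probabilities``
    enters the Gini index.
    """

    class_probabilities: Mapping[str, float]
    prior: Mapping[str, float] = field(default_factory=dict)
    class_sizes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = list(self.class_probabilities.values())
        if any(q < 0 or q > 1 for q in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {sum(probs)}, not 1")


def _plogp(q: float) -> float:
    # 0 * log2(0) := 0
    return 0.0 if q == 0.0 else -q * math.log2(q)


def info(c: BinaryClassCounts) -> float:
    """Binary entropy Info(p, n) = -D_p log2 D_p - D_n log2 D_n, in bits."""
    total = c.total
    return _plogp(c.p / total) + _plogp(c.n / total)


def expected_entropy(partition: Sequence[BinaryClassCounts]) -> float:
    """Size-weighted mean entropy of the cells of a partition."""
    if not partition:
        raise ValueError("empty partition")
    grand = sum(c.total for c in partition)
    return sum(c.total / grand * info(c) for c in partition)


def information_gain(
    parent: BinaryClassCounts, partition: Sequence[BinaryClassCounts]
) -> float:
    """Entropy reduction Info(parent) - E(partition); non-negative.

    Raises
    ------
    ValueError
        If the partition cells do not sum to the parent counts.
    """
    if (
        sum(c.p for c in partition) != parent.p
        or sum(c.n for c in partition) != parent.n
    ):
        raise ValueError("partition cells do not sum to the parent counts")
    return info(parent) - expected_entropy(partition)


def gini_index(d: NodeClassDistribution) -> float:
    """Gini impurity 1 - sum_i P(i|e)^2; 0 for a pure node."""
    return 1.0 - sum(q * q for q in d.class_probabilities.values())


def multiclass_entropy(sizes: Sequence[int]) -> float:
    """Entropy -sum_c (n_c/n) log2 (n_c/n) of class sizes, in bits.

    The multi-class generalization used when entropy drives tree building
    with one class per species.
    """
    if not sizes or any(s < 0 for s in sizes):
        raise ValueError("class sizes must be non-negative and non-empty")
    total = sum(sizes)
    if total == 0:
        raise ValueError("empty node")
    return sum(_plogp(s / total) for s in sizes)
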