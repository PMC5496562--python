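"""Greedy binary decision-tree induction over alignment columns.

Each internal node splits the species that reach it on one alignment
position: species carrying the *pivot* nucleotide there go left, everybody
else goes right.  The pivot is the base whose count is closest to half the
node size (the argmin of the score's diff term), so the cut is the most
balanced single-nucleotide cut the column offers; pooling the remaining
bases keeps the tree strictly binary even at tri-/tetra-allelic sites.
Recursion stops at singleton leaves, so a panel of N species always yields
exactly N leaves and N - 1 decision nodes.  Positions may be reused in
different subtrees.

The default node-scoring rule is the mid/diff/weight score
(:mod:`dtsb.scoring`); information gain and Gini impurity
(:mod:`dtsb.criteria`) are available as alternative criteria.  Ties are
always broken deterministically: lowest position index first, then
alphabetical pivot nucleotide.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .alignment import NUCLEOTIDES, AlignedSet
from .criteria import multiclass_entropy
from .errors import IndistinguishableSpeciesError, UnclassifiableError
from .profile import nucleotide_distribution
from .scoring import ScoreBreakdown, position_score

CRITERIA = ("dtsb", "gain", "gini")


@dataclass
class DecisionNode:
    """One node of the decision tree.

    A decision node carries ``position`` (1-based column), ``pivot`` (the
    left-branch nucleotide) and two children; a leaf carries exactly one
    ``species``.  ``level`` is the depth from the root (root = 1).
    """

    kind: str  # "decision" | "leaf"
    level: int
    position: int | None = None
    pivot: str | None = None
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None
    species: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.kind == "leaf"

    def walk(self) -> Iterator["DecisionNode"]:
        """Pre-order traversal (node, left subtree, right subtree)."""
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()

    def leaves(self) -> list["DecisionNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def decision_nodes(self) -> list["DecisionNode"]:
        return [n for n in self.walk() if not n.is_leaf]

    def depth(self) -> int:
        return max(leaf.level for leaf in self.leaves())

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"kind": "leaf", "level": self.level, "species": self.species}
        return {
            "kind": "decision",
            "level": self.level,
            "position": self.position,
            "pivot": self.pivot,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionNode":
        if d["kind"] == "leaf":
            return cls(kind="leaf", level=d["level"], species=d["species"])
        return cls(
            kind="decision",
            level=d["level"],
            position=d["position"],
            pivot=d["pivot"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _subset_counts(a: AlignedSet, rows: Sequence[int]) -> np.ndarray:
    """(4, M) per-base counts over the given rows."""
    sub = a.matrix[np.asarray(rows, dtype=int)]
    return np.stack([(sub == b).sum(axis=0) for b in NUCLEOTIDES]).astype(int)


def _candidate_positions(a: AlignedSet) -> list[int]:
    """Globally admissible positions: no gap/ambiguity in ANY sequence."""
    return [
        p
        for p in range(1, a.length + 1)
        if p not in nucleotide_distribution(a).excluded
    ]


def _gain_value(left: int, right: int) -> float:
    """Information gain of an (left, right) split with one class per row."""
    n = left + right
    parent = multiclass_entropy([1] * n)
    child = (
        left / n * multiclass_entropy([1] * left)
        + right / n * multiclass_entropy([1] * right)
    )
    return parent - child


def _gini_value(left: int, right: int) -> float:
    """Size-weighted child Gini with one class per row.

    Degenerate by construction: equals 1 - 2/n for every binary split of a
    node of n singleton classes, so this criterion reduces to the
    deterministic tie-break order.
    """
    n = left + right
    return left / n * (1 - 1 / left) + right / n * (1 - 1 / right)


def best_split(
    a: AlignedSet,
    row_subset: Sequence[int] | None = None,
    criterion: str = "dtsb",
    candidates: Sequence[int] | None = None,
) -> tuple[int, str]:
    """Choose the (position, pivot nucleotide) split for a node.

    Candidate columns are those free of gaps/ambiguity across the whole
    alignment AND variable within the node's row subset.  For the default
    criterion the column maximizing the mid/diff/weight score wins; ties go
    to the smallest position index, and the pivot is the base with count
    closest to mid (alphabetical on ties).  ``gain`` maximizes multi-class
    information gain and ``gini`` minimizes the weighted child Gini over
    all (position, base) cuts, with the same tie-break order.

    Raises
    ------
    IndistinguishableSpeciesError
        If no candidate column is variable within the subset.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    rows = list(range(a.n_species)) if row_subset is None else sorted(set(row_subset))
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to split")
    if candidates is None:
        candidates = _candidate_positions(a)
    n = len(rows)
    counts = _subset_counts(a, rows)

    best: tuple | None = None  # comparable key; lower is better
    best_choice: tuple[int, str] | None = None
    for p in candidates:
        col = counts[:, p - 1]
        if int(col.sum()) != n:  # gap within subset (globally excluded anyway)
            continue
        if int((col > 0).sum()) < 2:  # invariant within subset
            continue
        if criterion == "dtsb":
            sb = position_score(col, n, position=p)
            key = (-sb.score, p)
            choice = (p, sb.pivot)
            if best is None or key < best:
                best, best_choice = key, choice
        else:
            for i, base in enumerate(NUCLEOTIDES):
                c = int(col[i])
                if c == 0 or c == n:
                    continue
                value = (
                    -_gain_value(c, n - c)
                    if criterion == "gain"
                    else _gini_value(c, n - c)
                )
                key = (value, p, base)
                if best is None or key < best:
                    best, best_choice = key, (p, base)
    if best_choice is None:
        raise IndistinguishableSpeciesError(a.labels[r] for r in rows)
    return best_choice


def node_scores(
    a: AlignedSet,
    row_subset: Sequence[int] | None = None,
    candidates: Sequence[int] | None = None,
) -> list[ScoreBreakdown]:
    """Mid/diff/weight breakdown of every candidate column at a node."""
    rows = list(range(a.n_species)) if row_subset is None else sorted(set(row_subset))
    if candidates is None:
        candidates = _candidate_positions(a)
    counts = _subset_counts(a, rows)
    out = []
    for p in candidates:
        col = counts[:, p - 1]
        if int(col.sum()) == len(rows):
            out.append(position_score(col, len(rows), position=p))
    return out


def build_tree(a: AlignedSet, criterion: str = "dtsb") -> DecisionNode:
    """Grow the decision tree separating every species into its own leaf.

    Raises
    ------
    IndistinguishableSpeciesError
        If some subset of species cannot be separated at any admissible
        column (e.g. two identical sequences).
    """
    candidates = _candidate_positions(a)

    def grow(rows: list[int], level: int) -> DecisionNode:
        if len(rows) == 1:
            return DecisionNode(kind="leaf", level=level, species=a.labels[rows[0]])
        position, pivot = best_split(a, rows, criterion=criterion, candidates=candidates)
        left_rows = [r for r in rows if a.rows[r][position - 1] == pivot]
        right_rows = [r for r in rows if a.rows[r][position - 1] != pivot]
        return DecisionNode(
            kind="decision",
            level=level,
            position=position,
            pivot=pivot,
            left=grow(left_rows, level + 1),
            right=grow(right_rows, level + 1),
        )

    return grow(list(range(a.n_species)), level=1)


def classify(tree: DecisionNode, sequence: str) -> str:
    """Walk a query sequence down the tree and return its species label.

    The query must be in the same coordinate frame (and of the same length)
    as the alignment the tree was built from.

    Raises
    ------
    UnclassifiableError
        If the query carries a gap/ambiguity symbol at a decision position.
    """
    node = tree
    while not node.is_leaf:
        symbol = sequence[node.position - 1].upper()
        if symbol not in NUCLEOTIDES:
            raise UnclassifiableError(node.position, symbol)
        node = node.left if symbol == node.pivot else node.right
    return node.species


def save_tree(
    tree: DecisionNode,
    path: str | Path,
    alignment_length: int | None = None,
    criterion: str = "dtsb",
) -> None:
    """Serialize a tree (with metadata) as deterministic JSON."""
    doc = {
        "format": "dtsb-tree",
        "alignment_length": alignment_length,
        "criterion": criterion,
        "root": tree.to_dict(),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_tree(path: str | Path) -> tuple[DecisionNode, dict]:
    """Load a tree written by :func:`save_tree`; returns (root, metadata)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "dtsb-tree":
        raise ValueError(f"{path} is not a dtsb tree file")
    root = DecisionNode.from_dict(doc["root"])
    meta = {k: v for k, v in doc.items() if k != "root"}
    return root, meta


def to_dot(tree: DecisionNode) -> str:
    """Graphviz DOT rendering of the tree (decision nodes as circles)."""
    lines = ["digraph dtsb {", "  node [fontname=Helvetica];"]
    counter = 0

    def emit(node: DecisionNode) -> int:
        nonlocal counter
        my_id = counter
        counter += 1
        if node.is_leaf:
            lines.append(f'  n{my_id} [shape=box, label="{node.species}"];')
        else:
            lines.append(f'  n{my_id} [shape=circle, label="p{node.position}"];')
            left_id = emit(node.left)
            right_id = emit(node.right)
            lines.append(f'  n{my_id} -> n{left_id} [label="{node.pivot}"];')
            lines.append(f'  n{my_id} -> n{right_id} [label="not {node.pivot}"];')
        return my_id

    emit(tree)
    lines.append("}")
    return "\n".join(lines) + "\n"
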