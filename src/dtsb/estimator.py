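"""Scikit-learn style estimator wrapping the full barcoding pipeline.

:class:`SNPBarcodeClassifier` fits the decision tree on a species panel
(one aligned sequence per species) and predicts species labels for aligned
query sequences by walking the tree.  It follows the scikit-learn estimator
contract — ``get_params``/``set_params``, fitted attributes with trailing
underscores, ``clone``-ability — so it composes with sklearn model
selection utilities, although its features are alignment columns rather
than numeric vectors.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .alignment import AlignedSet, trim_common_region
from .barcode import SNPBarcode, extract_barcodes
from .profile import (
    BarcodeBounds,
    barcode_length_bounds,
    nucleotide_distribution,
    variable_positions,
)
from .tree import CRITERIA, DecisionNode, build_tree, classify


def _as_sequences(X) -> list[str]:
    if isinstance(X, str):
        raise ValueError("X must be a collection of sequences, not one string")
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return ["".join(row) for row in X.astype("U1")]
    return [str(s) for s in X]


class SNPBarcodeClassifier(ClassifierMixin, BaseEstimator):
    """Species classifier via greedy SNP decision-tree barcoding.

    Parameters
    ----------
    criterion : {"dtsb", "gain", "gini"}, default "dtsb"
        Node-scoring rule: the mid/diff/weight score (default), multi-class
        information gain, or Gini impurity.
    trim : bool, default True
        Trim the training alignment to its blunt-ended common region before
        building the tree (recommended unless the input is pre-trimmed).

    Attributes
    ----------
    alignment_ : AlignedSet
        The (possibly trimmed) training panel; its columns are the
        coordinate frame of all positions.
    tree_ : DecisionNode
        Root of the fitted decision tree (N leaves, N - 1 decision nodes).
    barcodes_ : list of SNPBarcode
        One species-specific SNP barcode per training species.
    classes_ : ndarray of str
        Sorted species labels.
    variable_positions_ : list of int
        SNP sites of the trimmed panel (1-based).
    bounds_ : BarcodeBounds
        The [ceil(N/4), N - 1] interval bracketing achievable tree sizes.
    n_features_in_ : int
        Length of the training sequences as passed in (pre-trim).

    Examples
    --------
    >>> from dtsb.simulate import figure3_fixture
    >>> clf = SNPBarcodeClassifier().fit(figure3_fixture())
    >>> clf.tree_.position  # root decision position
    6
    >>> clf.predict(["CAAAACAA"])[0]
    'S1'
    """

    def __init__(self, criterion: str = "dtsb", trim: bool = True):
        self.criterion = criterion
        self.trim = trim

    def fit(self, X, y: Sequence[str] | None = None) -> "SNPBarcodeClassifier":
        """Build the decision tree and barcodes from a species panel.

        Parameters
        ----------
        X : AlignedSet, or collection of N aligned sequences (strings or an
            (N, M) character array)
        y : sequence of N species labels; required (and used) only when X
            is not an AlignedSet.
        """
        if self.criterion not in CRITERIA:
            raise ValueError(
                f"criterion must be one of {CRITERIA}, got {self.criterion!r}"
            )
        if isinstance(X, AlignedSet):
            panel = X
        else:
            rows = _as_sequences(X)
            if y is None:
                raise ValueError("y (species labels) required unless X is an AlignedSet")
            if len(y) != len(rows):
                raise ValueError(f"{len(rows)} sequences but {len(y)} labels")
            panel = AlignedSet(labels=tuple(str(l) for l in y), rows=tuple(rows))
        self.n_features_in_ = panel.length
        raw_offset = panel.origin_offset
        if self.trim:
            panel = trim_common_region(panel)
        self._trim_start = panel.origin_offset - raw_offset
        self.alignment_ = panel
        self.alignment_length_ = panel.length
        dist = nucleotide_distribution(panel)
        self.variable_positions_ = variable_positions(dist)
        self.site_distribution_ = dist
        self.bounds_ = barcode_length_bounds(panel.n_species)
        self.tree_ = build_tree(panel, criterion=self.criterion)
        self.barcodes_ = extract_barcodes(self.tree_, panel)
        self.classes_ = np.array(sorted(panel.labels), dtype=object)
        return self

    def _to_frame(self, seq: str) -> str:
        """Map a query onto the fitted (trimmed) coordinate frame."""
        if len(seq) == self.alignment_length_:
            return seq
        if len(seq) == self.n_features_in_:
            return seq[self._trim_start : self._trim_start + self.alignment_length_]
        raise ValueError(
            f"query length {len(seq)} matches neither the training length "
            f"{self.n_features_in_} nor the trimmed length {self.alignment_length_}"
        )

    def predict(self, X) -> np.ndarray:
        """Species label per query sequence (tree walk).

        Queries may be given in the original training frame or already
        trimmed.  Raises :class:`~dtsb.errors.UnclassifiableError` if a
        query carries a gap/ambiguity symbol at a decision position.
        """
        if not hasattr(self, "tree_"):
            raise ValueError("estimator is not fitted; call fit first")
        rows = _as_sequences(X)
        return np.array(
            [classify(self.tree_, self._to_frame(s.upper())) for s in rows],
            dtype=object,
        )

    def max_barcode_length(self) -> int:
        """Longest deduplicated per-species barcode (number of positions)."""
        if not hasattr(self, "barcodes_"):
            raise ValueError("estimator is not fitted; call fit first")
        return max(len(b.sorted_entries) for b in self.barcodes_)

    def barcode_position_union(self) -> list[int]:
        """Sorted union of all decision positions used by the tree."""
        if not hasattr(self, "tree_"):
            raise ValueError("estimator is not fitted; call fit first")
        return sorted({n.position for n in self.tree_.decision_nodes()})
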