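"""Per-position nucleotide distributions, SNP sites, and panel combinatorics.

The distribution ``D`` is a 4 x M count matrix: for each alignment column p,
how many sequences of the (sub)set carry A, C, G or T there.  Columns holding
any gap or ambiguity symbol are excluded from SNP candidacy — counts are
defined only over the four canonical bases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment import NUCLEOTIDES, AlignedSet

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class SiteDistribution:
    """Nucleotide counts per alignment column for a set of rows.

    Attributes
    ----------
    counts : (4, M) int array
        Rows A, C, G, T; ``counts[i, p-1]`` is the number of subset
        sequences carrying base i at 1-based position p.
    n_rows : int
        Size of the row subset the counts were tallied over.
    excluded : frozenset of int
        1-based positions where any subset row holds a gap or ambiguity
        symbol; at every other position the four counts sum to ``n_rows``.
    """

    counts: np.ndarray
    n_rows: int
    excluded: frozenset[int]

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def column(self, position: int) -> tuple[int, int, int, int]:
        """(f_A, f_C, f_G, f_T) at 1-based `position`."""
        return tuple(int(c) for c in self.counts[:, position - 1])


@dataclass(frozen=True)
class BarcodeBounds:
    """Bounds on the number of SNP sites needed to separate N species.

    ``p_min = ceil(N/4)`` is the most parsimonious case (every site splits
    four ways); ``p_max = N - 1`` is the least informative case (each site
    peels off a single species).
    """

    p_min: int
    p_max: int


def nucleotide_distribution(
    a: AlignedSet, row_subset: Iterable[int] | None = None
) -> SiteDistribution:
    """Tally A/C/G/T occurrences per column over a subset of rows.

    Parameters
    ----------
    a : AlignedSet
    row_subset : iterable of int, optional
        0-based row indices; defaults to all rows.

    Raises
    ------
    ValueError
        On an empty or out-of-range subset.
    """
    if row_subset is None:
        idx = np.arange(a.n_species)
    else:
        idx = np.asarray(sorted(set(row_subset)), dtype=int)
        if idx.size == 0:
            raise ValueError("empty row subset")
        if idx.min() < 0 or idx.max() >= a.n_species:
            raise ValueError("row subset out of range")
    sub = a.matrix[idx]
    counts = np.stack([(sub == b).sum(axis=0) for b in NUCLEOTIDES]).astype(int)
    covered = counts.sum(axis=0)
    excluded = frozenset(int(p) for p in np.nonzero(covered < idx.size)[0] + 1)
    return SiteDistribution(counts=counts, n_rows=int(idx.size), excluded=excluded)


def variable_positions(d: SiteDistribution) -> list[int]:
    """All non-excluded positions with >= 2 nucleotide types present, ascending.

    These are the SNP sites of the panel: the candidate decision positions.
    """
    n_types = (d.counts > 0).sum(axis=0)
    positions = [int(p) for p in np.nonzero(n_types >= 2)[0] + 1]
    return [p for p in positions if p not in d.excluded]


def barcode_length_bounds(n_species: int) -> BarcodeBounds:
    """The interval P = [p_min, p_max] of decision-node counts for N species.

    p_min = ceil(N/4) (a 4-state site can separate at most 4 groups);
    p_max = N - 1 (a binary tree with N singleton leaves has N - 1
    internal nodes).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    return BarcodeBounds(p_min=math.ceil(n_species / 4), p_max=n_species - 1)


def snp_combination_count(n_species: int, n_snps: int) -> int:
    """Number of multisets of size N-1 drawn from M SNP sites with repetition.

    The worst-case tree needs N - 1 decision nodes, each choosing one of the
    M SNP positions with repetition allowed: H(M, N-1) = C(N - 1 + M - 1,
    N - 1).  Exact integer arithmetic.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if n_snps < 1:
        raise ValueError("need at least 1 SNP site")
    return math.comb(n_species - 1 + n_snps - 1, n_species - 1)


def site_table(d: SiteDistribution) -> pd.DataFrame:
    """The distribution as a tidy per-position table."""
    m = d.length
    return pd.DataFrame(
        {
            "position": np.arange(1, m + 1),
            "count_A": d.counts[0],
            "count_C": d.counts[1],
            "count_G": d.counts[2],
            "count_T": d.counts[3],
            "excluded": [int(p in d.excluded) for p in range(1, m + 1)],
        }
    )


def write_site_table(d: SiteDistribution, path: str | Path) -> None:
    """Write the per-position distribution as TSV."""
    site_table(d).to_csv(path, sep="\t", index=False)
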