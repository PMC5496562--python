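"""Independent brute-force oracles, deliberately naive and separate from
the library's implementation paths."""

from fractions import Fraction
from itertools import combinations_with_replacement

_WEIGHTS = {1: Fraction(0), 2: Fraction(1), 3: Fraction(66, 100), 4: Fraction(33, 100)}
_BASES = "ACGT"


def naive_score(column: str) -> Fraction:
    """Mid/diff/weight score of one column given its symbols, via direct
    per-symbol counting (no numpy, no shared code)."""
    n = len(column)
    mid = Fraction(n, 2)
    counts = [column.count(b) for b in _BASES]
    diff = min(abs(mid - c) for c in counts)
    n_types = len({s for s in column if s in _BASES})
    return (mid - diff) / mid + _WEIGHTS[n_types]


def naive_pivot(column: str) -> str:
    """Base with count closest to n/2, alphabetical tie-break."""
    n = len(column)
    mid = Fraction(n, 2)
    best = min(_BASES, key=lambda b: (abs(mid - column.count(b)), b))
    return best


def brute_force_best_split(rows, candidates):
    """Exhaustive argmax of the score over candidate 1-based positions for
    the given sequence rows; returns (position, pivot) or None if no
    candidate is variable."""
    best = None
    for p in candidates:
        column = "".join(r[p - 1] for r in rows)
        if any(s not in _BASES for s in column):
            continue
        if len(set(column)) < 2:
            continue
        score = naive_score(column)
        if best is None or score > best[0]:
            best = (score, p, naive_pivot(column))
    if best is None:
        return None
    return best[1], best[2]


def count_multisets(n_items: int, size: int) -> int:
    """Number of multisets of `size` drawn from `n_items` types, by
    explicit enumeration."""
    return sum(1 for _ in combinations_with_replacement(range(n_items), size))
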