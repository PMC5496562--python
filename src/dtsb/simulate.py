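"""Deterministic synthetic alignments for testing and demonstration.

Three generators:

* :func:`figure3_fixture` — a fixed 8-species x 8-position toy panel whose
  per-position allele counts reproduce the worked example of the method
  (position 1 counts (0,7,0,1), position 6 counts (0,4,0,4), root split at
  position 6 with the maximal score 2).
* :func:`random_panel` — seeded random species panels: a uniform-random
  root sequence with independent per-site substitutions per species,
  rejection-sampled until all species are pairwise distinguishable.
* :func:`protruding_ends_fixture` — staggered terminal gaps with a known
  common region, for exercising trimming.

All generators are pure functions of their arguments (bit-identical output
for a given seed).  The random model is deliberately simple — no
transition/transversion bias, no rate heterogeneity, no indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import NUCLEOTIDES, AlignedSet

#: rejection-sampling bound before giving up on a FixtureSpec
MAX_ATTEMPTS = 1000

# 8 species x 8 positions, consistent with the worked example's printed
# constraints: position 1 -> (A,C,G,T) = (0,7,0,1); position 6 -> (0,4,0,4);
# all rows pairwise distinct; the best-scoring root column is position 6
# (score 2; position 8 ties and loses the lowest-index tie-break).
_FIGURE3_ROWS = (
    "CAAAACAA",
    "CAAAACAC",
    "CCAAACAA",
    "CCAAACAC",
    "CAAAATAA",
    "CAAAATAC",
    "CCAACTAA",
    "TAAACTAC",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random species panel.

    Attributes
    ----------
    n_species, n_sites : int
    seed : int
        Seeds a private NumPy generator; same spec -> same panel.
    mutation_rate : float
        Per-site probability that a species differs from the panel's root
        sequence (uniform over the three alternative bases).
    site_constraints : dict position -> (f_A, f_C, f_G, f_T)
        Optional exact allele counts to impose at given 1-based positions;
        each tuple must sum to ``n_species``.
    """

    n_species: int
    n_sites: int
    seed: int = 0
    mutation_rate: float = 0.1
    site_constraints: dict[int, tuple[int, int, int, int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_sites < 1:
            raise ValueError("need n_species >= 2 and n_sites >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        for pos, counts in self.site_constraints.items():
            if not 1 <= pos <= self.n_sites:
                raise ValueError(f"constrained position {pos} out of range")
            if len(counts) != 4 or sum(counts) != self.n_species:
                raise ValueError(
                    f"constraint at position {pos} must be 4 counts summing "
                    f"to {self.n_species}"
                )


def figure3_fixture() -> AlignedSet:
    """The fixed 8x8 worked-example panel (species S1..S8)."""
    return AlignedSet(
        labels=tuple(f"S{i}" for i in range(1, 9)), rows=_FIGURE3_ROWS
    )


def random_panel(spec: FixtureSpec) -> AlignedSet:
    """Seed-deterministic random panel with pairwise-distinguishable species.

    Draws a root sequence uniformly over {A,C,G,T}, applies independent
    per-site substitutions per species, imposes any per-site count
    constraints, and rejection-samples until all rows are pairwise
    distinct (every pair then differs at >= 1 gap-free site, so the panel
    is discriminable).

    Raises
    ------
    RuntimeError
        If no discriminable panel is found within MAX_ATTEMPTS draws.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list(NUCLEOTIDES), dtype="U1")
    n, m = spec.n_species, spec.n_sites
    for _ in range(MAX_ATTEMPTS):
        root = rng.integers(0, 4, size=m)
        matrix = np.tile(root, (n, 1))
        mutate = rng.random((n, m)) < spec.mutation_rate
        # substitute with a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=(n, m))
        matrix = np.where(mutate, (matrix + shifts) % 4, matrix)
        for pos, counts in spec.site_constraints.items():
            column = np.repeat(np.arange(4), counts)
            matrix[:, pos - 1] = rng.permutation(column)
        rows = tuple("".join(bases[matrix[i]]) for i in range(n))
        if len(set(rows)) == n:
            return AlignedSet(
                labels=tuple(f"S{i}" for i in range(1, n + 1)), rows=rows
            )
    raise RuntimeError(
        f"no discriminable panel found in {MAX_ATTEMPTS} attempts for {spec}"
    )


def protruding_ends_fixture() -> AlignedSet:
    """Three sequences with staggered 5'/3' overhangs.

    The common region is columns 3..8 by construction; trimming yields the
    6-column block ("ACGTCA", "ACGACA", "ACGTCC") with origin_offset 2.
    """
    return AlignedSet(
        labels=("S1", "S2", "S3"),
        rows=("--ACGTCATT", "GGACGACATT", "GGACGTCC--"),
    )
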