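# Methods

## Problem setting

A *panel* is a multiple alignment holding exactly one representative DNA
barcode sequence (e.g. mitochondrial COI) per species.  The goal is a
species-specific *SNP barcode*: for each species, the minimal ordered set
of (alignment position, nucleotide) pairs that distinguishes it from every
other panel member.  This is a within-panel diagnosis problem — the
barcodes carry no information about species outside the panel, and with
one sequence per species there is no model of within-species
polymorphism.  Alignment is an upstream step (MAFFT, ClustalW, ...); the
package consumes the aligned multi-FASTA.

## Coordinate frame and trimming

Sequences deposited for different species rarely start and end at the
same offset, so the alignment has protruding 5′/3′ ends.  Trimming removes
every column that lies before some row's first non-gap symbol or after
some row's last; the surviving *common region* is renumbered 1..M′ and is
the coordinate frame for every position the package reports.  Internal
gaps are deliberately **not** trimmed: a column containing any gap or
ambiguity symbol (N, R, Y, ...) anywhere in the panel is instead excluded
from split candidacy, since the per-base counts that drive the score are
defined only over A/C/G/T.  Trimming is idempotent, and an input whose
sequences share no column at all is rejected ("no common region").

## The position score

At a tree node holding n sequences, column p with counts
(f_A, f_C, f_G, f_T) scores

    score_p = (mid_p − diff_p) / mid_p + weight_p
    mid_p   = n / 2
    diff_p  = min_i |mid_p − f_i^p|
    weight_p = 0 / 1 / 0.66 / 0.33  for 1 / 2 / 3 / 4 types present

The first term measures how close the best single-base cut comes to an
even halving (1 when some base occurs exactly n/2 times, 0 for an
invariant column); the weight rewards low allelic complexity, with a
biallelic site worth the full bonus.  Scores therefore lie in [0, 2] and
only a perfectly balanced biallelic column attains 2.  The diff term is
an absolute deviation: counts above mid are as imbalanced as counts
below it, which is also what the quantity's worked arithmetic (|4 − 7| =
3 for counts (0,7,0,1) at n = 8) requires.

Two numerical choices matter:

* **Exact arithmetic.**  Scores are `fractions.Fraction`s, with the
  weights represented as the exact decimals 66/100 and 33/100 (the
  published constants, not 2/3 and 1/3).  Score ties are therefore
  detected exactly and tie-breaking cannot depend on floating-point
  platform details.
* **Deterministic tie-breaks.**  Equal-score columns resolve to the
  lowest position index; equal-deviation bases resolve alphabetically
  (A < C < G < T).  The procedure is a pure function of the panel.

## Tree induction

Greedy top-down: at each node, score every admissible column (globally
gap-free AND variable within the node's subset), pick the argmax, and
send the species carrying the *pivot* base — the argmin of the diff term,
i.e. the base whose count is closest to n/2 — to the left child,
everything else to the right.  At a variable column the pivot's count is
strictly between 0 and n (a base with count 0 or n can never attain the
minimum deviation there), so both children are non-empty and recursion
terminates in singleton leaves: N leaves and N − 1 decision nodes,
always.  Tri- and tetra-allelic columns still produce a binary split —
the non-pivot bases are pooled — which keeps the tree strictly binary at
the cost of sometimes needing the same column again deeper down;
positions may be reused freely across subtrees.

If some subset of species reaches a node with no variable admissible
column (e.g. two identical sequences, or species differing only at gapped
columns), the build aborts with the offending species named.  There is no
pruning, no depth cap and no minimum node size: the tree must separate
everything, and its size is bracketed by p_min = ⌈N/4⌉ (every node a
4-way-informative site, in the binary-pooled sense) and p_max = N − 1
(one species peeled off per node).  The number of worst-case node
multisets available from M SNP sites, C(N − 1 + M − 1, N − 1), is
computed in exact integer arithmetic.

## Alternative split criteria

Information gain and Gini impurity are provided as pluggable criteria for
comparison.  Both are evaluated over all (column, base) binary cuts with
the same tie-break order.  With one sequence per species every row is its
own class, which has two consequences worth knowing:

* *Gain* reduces to a pure balance measure — log2 n minus the
  size-weighted child entropies log2 n_L, log2 n_R — and so behaves much
  like the default score without the allele-complexity bonus.
* *Gini* is **degenerate**: the size-weighted child impurity of any
  binary split of n singleton classes is 1 − 2/n regardless of the split,
  so the criterion decays to the tie-break order (lowest position,
  alphabetical base).  It is retained for completeness; the resulting
  trees still satisfy every structural guarantee (N singleton leaves,
  self-consistent classification) but their node choices are not
  score-driven.

Criteria are never mixed within one tree.  The binary-target entropy
closed forms (`info`, `expected_entropy`, `information_gain`) are kept
exactly as printed in the classical formulation, in bits; the multi-class
generalization used during tree building is labelled as such.

## Barcodes

A species' barcode lists, for each decision node on its root-to-leaf
path, the level, the position and the species' **own** base there (not
the pivot; the branch taken is recoverable by comparison with the
pivot).  Because positions can recur on a path, the raw level-ordered
barcode may repeat a position — necessarily with the same base — and the
position-sorted view collapses each position to one entry (first
occurrence kept).  Sorted barcodes are rendered as `p12:A;p87:T;...`, a
textual stand-in for 1-D barcode imagery, and serialized as TSV/JSON.

Matching a query against a barcode set (query carries the barcode's base
at every barcode position) classifies every training row identically to
the tree walk, and all sorted barcode strings within a panel are pairwise
distinct; both facts are enforced by tests over hundreds of seeded random
panels.  A query matching nothing reports `unknown`; matching more than
one barcode is impossible for tree-derived sets and raises a corruption
error.

## The estimator

`SNPBarcodeClassifier(criterion="dtsb", trim=True)` wraps the pipeline in
the scikit-learn estimator contract (`fit`, `predict`, `score`,
`get_params`/`clone`); fitted state lives in trailing-underscore
attributes (`tree_`, `barcodes_`, `classes_`, `variable_positions_`,
`bounds_`).  `fit` accepts an `AlignedSet` or raw sequences plus labels;
`predict` accepts queries in either the original or the trimmed
coordinate frame and walks them down the tree, raising an
"unclassifiable" error when a query holds a gap/ambiguity symbol at a
decision position rather than guessing a branch.

## Synthetic panels

The generator serves two purposes.  `figure3_fixture()` is a fixed 8 × 8
panel reproducing the method's worked example at the level of its printed
quantities: position-1 counts (0,7,0,1) (score 1.25), position-6 counts
(0,4,0,4) (score 2, the root split), eight pairwise-distinct rows.  The
exact sequence matrix behind the original example is not published, so
the fixture is *a* matrix meeting every printed constraint, not a copy;
only printed quantities are asserted against it.  In this fixture
position 8 also scores 2 at the root and loses the lowest-index
tie-break, exercising that rule.

`random_panel(FixtureSpec)` draws a root sequence uniformly over
{A,C,G,T} and applies independent per-site substitutions per species
(uniform over the three alternative bases), rejection-sampling up to
1000 attempts until all rows are pairwise distinct.  Optional per-site
allele-count constraints are imposed by shuffling a prescribed column
multiset.  The default substitution rate is **0.1 per site**, chosen to
mimic congeneric barcode divergence (a 17-species COI panel typically
shows on the order of a quarter of its sites variable, which a 0.1
per-species rate reproduces at that panel size).  The stress-test suites
that push panels to extremes — up to 20 species on as few as 4 sites —
pass `mutation_rate=0.5` explicitly, because at realistic divergence that
many distinct species cannot exist on so few sites at all; the high-rate
regime is the condition under which such panels are realizable.  All
generators are pure functions of their spec (bit-identical across runs).

What the generator does *not* emulate: transition/transversion bias,
among-site rate heterogeneity, indels/internal gaps, phylogenetic
correlation between species, and within-species variation.  Passing tests
on these panels therefore demonstrate the algorithm's combinatorial
guarantees (uniqueness, self-consistency, greedy optimality per node,
shape bounds), not its behaviour on the quirks of real alignments —
real-data properties such as a specific trimmed length or SNP count
depend on the upstream alignment and are only reproducible from it.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on generated data: the
8 × 8 worked-example panel, hypothesis-driven panels up to 12 species ×
60 sites, a 200-panel sweep with N ∈ [2, 20] and M ∈ [4, 200] (each node
of each tree cross-checked against a brute-force argmax oracle), and a
seeded 17-species × 185-site end-to-end round trip mirroring the scale of
the published pigeon panel.

## Known limitations

* Greedy induction is locally optimal per node; it does not guarantee the
  globally shortest barcode set (finding that is a set-cover-like
  problem).
* One sequence per species: a polymorphic site within a real species can
  invalidate a barcode entry; users should choose representatives or
  pre-collapse haplotypes.
* Queries must be aligned to the panel's coordinate frame; there is no
  built-in aligner.
* IUPAC ambiguity codes are treated as missing (column excluded from
  candidacy; query unclassifiable at a decision position), never as
  partial matches.
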