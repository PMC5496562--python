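# dtsb — decision tree-based SNP barcoding

Species identification with DNA barcodes (typically the ~650 bp
mitochondrial COI region) normally compares whole sequences, most of which
is invariant and uninformative within a group of related species.  `dtsb`
compresses a panel of aligned barcode sequences — one representative per
species — into **species-specific SNP barcodes**: for each species, the
short ordered set of (alignment position, nucleotide) pairs that uniquely
tags it within the panel.  A panel of N species needs between ⌈N/4⌉ and
N − 1 diagnostic sites, versus hundreds of bases for the full barcode.

It is aimed at people building rapid species-diagnostic assays (food
authentication, forensics, biodiversity screening) from an existing
alignment of known species.  The barcodes are valid only *within* the
panel they were built from; the method does not identify species absent
from the panel.

## Method

Given an alignment **X** of N species × M columns, the per-column
nucleotide counts f_i^p (i ∈ {A,C,G,T}) are tallied into a 4×M
distribution **D**.  A greedy binary decision tree is grown from the root
(all species): at each node of size n, every admissible column p is scored

    score_p = (mid_p − diff_p) / mid_p + weight_p

where

* mid_p = n / 2,
* diff_p = min_i |mid_p − f_i^p|  (the imbalance of the best
  single-nucleotide cut),
* weight_p ∈ {0, 1, 0.66, 0.33} for 1, 2, 3, 4 nucleotide types present.

Scores lie in [0, 2]; a perfectly balanced biallelic column attains 2.
The column with the maximal score is chosen (ties → lowest position), the
species carrying the *pivot* nucleotide (the argmin of the diff term) go
left, all others right, and the procedure recurses until every leaf holds
one species.  Columns may be reused in different subtrees.  Each species'
barcode is then read off its root-to-leaf path and reported both in
decision order and position-sorted with duplicates collapsed.  Classical
information-gain and Gini criteria are available as alternative split
rules for comparison.

Candidate columns are those free of gaps/ambiguity codes across the panel;
protruding 5′/3′ alignment ends are trimmed to the blunt-ended common
region, which is the coordinate frame for all positions (1-based).

## Worked example

The bundled 8-species × 8-position demonstration panel reproduces the
method's worked example: position 1 has counts (A,C,G,T) = (0,7,0,1),
giving mid = 4, diff = 3, weight = 1 and score (4−3)/4 + 1 = **1.25**,
while position 6 with counts (0,4,0,4) is perfectly balanced and scores
(4−0)/4 + 1 = **2**, the maximum — so the tree roots there.

```python
from dtsb import SNPBarcodeClassifier
from dtsb.simulate import figure3_fixture

clf = SNPBarcodeClassifier().fit(figure3_fixture())
clf.tree_.position          # 6  — root decision column
clf.predict(["CAAAACAA"])   # array(['S1'], dtype=object)
```

The same run from the shell:

```
$ python -c "from dtsb.alignment import write_aligned_fasta; \
             from dtsb.simulate import figure3_fixture; \
             write_aligned_fasta(figure3_fixture(), 'panel.fasta')"
$ dtsb build --input panel.fasta --outdir out
species (N): 8
alignment length (M): 8
trimmed common region (M'): 8
variable (SNP) positions: 5
decision-node bounds [p_min, p_max]: [2, 7]
barcode S1: 3 positions (p2:A;p6:C;p8:A)
barcode S2: 3 positions (p2:A;p6:C;p8:C)
barcode S3: 3 positions (p2:C;p6:C;p8:A)
barcode S4: 3 positions (p2:C;p6:C;p8:C)
barcode S5: 3 positions (p5:A;p6:T;p8:A)
barcode S6: 3 positions (p5:A;p6:T;p8:C)
barcode S7: 3 positions (p1:C;p5:C;p6:T)
barcode S8: 3 positions (p1:T;p5:C;p6:T)
wrote out/tree.json, out/barcodes.tsv, out/sites.tsv
```

Each species is tagged by just 3 of the 8 columns (within the [2, 7]
bounds), every tag is distinct, and `dtsb classify --tree out/tree.json
--input panel.fasta` assigns every panel sequence back to its own species.
`dtsb simulate` writes seeded synthetic panels for experimentation.

For a real panel, align your per-species sequences externally (e.g. MAFFT
or ClustalW), then run `dtsb build` on the aligned FASTA.  On the
published 17-species pigeon (Columbidae) COI panel this workflow trims to
a 652 bp common region and tags each species with roughly a dozen SNP
positions out of the full barcode.

## Layout

* `dtsb.alignment` — aligned FASTA I/O, common-region trimming
* `dtsb.profile` — nucleotide distributions, SNP sites, panel combinatorics
* `dtsb.scoring` — the mid/diff/weight position score (exact rationals)
* `dtsb.criteria` — information gain and Gini, as pluggable alternatives
* `dtsb.tree` — greedy tree induction, classification, JSON/DOT export
* `dtsb.barcode` — barcode extraction, sorting/dedup, matching, TSV/JSON
* `dtsb.estimator` — `SNPBarcodeClassifier`, the scikit-learn-style front end
* `dtsb.simulate` — deterministic synthetic panels
* `dtsb.cli` — the `dtsb` command (`build` / `classify` / `simulate`)

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
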