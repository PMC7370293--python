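# Methods

## Residue cluster classes

A protein chain is reduced to a residue contact graph: nodes are the
residues that survive filtering (standard amino acids, heavy atoms, one
altloc conformer), and an edge joins residues *i* ≠ *j* whenever the
minimum Euclidean distance over their selected atom sets is ≤ the cutoff
(inclusive).  Two atom selections are supported: `noSC` uses the backbone
atoms N, CA, C, O; `SC` uses every heavy atom.  The cutoff is scanned over
4–15 Å in 1 Å steps, so each chain has 12 × 2 = 24 contact-graph
representations.  Sequence-adjacent residues are eligible contacts like any
other pair; the distance criterion is the minimum atom–atom distance (the
convention consistent with "including the sidechain atoms"), isolated
behind `contact_graph` so a representative-point variant could be swapped
in without touching anything downstream.

The RCC vector counts the maximal cliques of this graph, grouped by size
(3–6) and classified by sequence proximity.  Proximity is defined on
consecutive sequence indices (difference exactly 1): the members of a clique
split into maximal runs of consecutive positions, and the multiset of run
lengths is an integer partition of the clique size.  Three scattered
residues give [1,1,1]; three consecutive ones give [3].  The partitions of
3, 4, 5, 6 number 3, 5, 7 and 11, hence 26 classes.  The canonical order is
sizes ascending, partitions within a size in descending lexicographic order,
so RCC1 = (3, [3]), RCC7 = (4, [2,1,1]), RCC26 = (6, [1,1,1,1,1,1]).  Only
the size blocks are fixed by the construction; the within-block order is a
package convention, kept stable and isolated in `PARTITION_CLASS_TABLE`.

Maximal cliques are enumerated by Bron–Kerbosch with pivoting (networkx).
Cliques of size < 3 carry no cluster information; cliques of size > 6 fall
outside the class table and are discarded whole (truncating or decomposing
them would break the identity sum(counts) = number of counted maximal
cliques).  A debug counter records how many were discarded.

Sequence indices default to sequential renumbering 1..L after filtering, so
gaps in author numbering collapse; `numbering="author"` preserves the
printed numbers instead (it then requires them to be strictly increasing).
The choice matters for the proximity partition whenever a chain has gaps;
sequential is the default because it is deterministic on any parseable
file.

## Pair features and scaling

A protein pair is represented either by the elementwise **sum** of the two
RCC vectors (26 features, order-independent) or by their **concatenation**
(52 features, order-sensitive; the input pair order is preserved and never
canonicalised — a documented caveat).  Combining requires both vectors to
share cutoff and atom mode.

Datasets are kept raw, min-max normalised to [0, 1], or standardised to
zero mean/unit variance.  Scalers are always fitted on the training
partition and applied frozen to test data; test values may leave [0, 1]
under normalisation.  Degenerate features are made total: a zero-range
feature normalises to 0 and a zero-variance feature standardises to 0,
never NaN.

## Imbalance sampling and the experiment grids

The sampling experiment is a cross product over 8 representation
combinations (cutoffs {7, 8} Å × {SC, noSC} × {sum, concat}):

* undersampling branch — positives sampled without replacement down to 1:1,
  2:1 or 3:1 against the negatives (all negatives kept), 3 seeded
  replicates, 3 scalings: 8 × 3 × 3 × 3 = 216 training sets;
* oversampling branch — classical SMOTE on the negatives of the replicate's
  1:1 undersample, factors 2 and 3 (output = one unmodified copy of every
  original plus synthetics on segments toward one of the k = 5 nearest
  minority neighbours, one u ~ U[0,1) per synthetic): 8 × 2 × 3 × 3 = 144,
  for 360 training sets in all.  Test sets are the unsampled cross product
  8 × 3 scalings = 24.

Replicate seeds derive from a base seed via CRC32 of the configuration
tokens, so the grid is a pure function of its spec and the 1:2/1:3
oversamples provably share the 1:1 replicate's sample.

The domain-aware splitter groups positive pairs by the unordered pair of
their proteins' domain-set annotations and sends at most half of each group
to test (largest groups first), so every tested domain combination has at
least as many training examples and singletons train only.  Negatives are
either copied to both partitions (redundant protocol) or split 80/20 by a
seeded permutation of unique pairs (non-redundant protocol).  Redundancy
removal deduplicates feature vectors within each partition (first
occurrence wins) and drops any test vector that equals a training vector.

## Separability diagnostics and feature screening

For two labelled clouds the package reports the negative set's diameter D
(largest within-set Euclidean distance), the smallest between-set distance
d, and the flag d > D ("distance separable": the gap exceeds the negative
set's spread).  The positive set's diameter is reported alongside since the
designation is a convention.  Linear separability is decided exactly as LP
feasibility of w·x + b ≥ 1 on one class and ≤ −1 on the other (any strict
separator rescales to this margin), so the answer carries no soft-margin
tolerance; the witness hyperplane is returned when feasible.

Per-feature screening uses the two-sided rank-sum (Mann–Whitney/Wilcoxon)
test.  Below a combined sample size of 20 the p-value is computed by full
enumeration of group assignments over tie-averaged ranks — exact with ties,
where textbook exact tables are not; the permutation distribution of U is
symmetric about mn/2, and the two-sided p is the probability of a deviation
at least as large as observed.  At n ≥ 20 the tie-corrected normal
approximation with continuity correction is used.  A feature constant
across both classes gets p = 1 and a `degenerate` flag.  Adjustment across
the 26 (52) features is Bonferroni or Benjamini–Hochberg; BH significance
flags are always a superset of Bonferroni flags at the same alpha.  Alpha
defaults to 0.05.  The nonzero-fraction profile (share of instances with a
strictly nonzero value, per feature) summarises sparsity across the grid.

## Classification

The classifier is locally weighted learning reconstructed as kernel-weighted
kNN: a query's k nearest training instances (Euclidean) vote with weights
w_i = max(0, 1 − d_i/d_cut) under the linear kernel, where d_cut is the
distance to the (k+1)-th neighbour (or the farthest neighbour when k equals
the training size); the constant kernel is plain majority vote.  If every
weight vanishes (all neighbours at d_cut, e.g. a single-instance training
set) weights fall back to uniform.  Score ties resolve to the negative
class — conservative in a positives-dominated domain — and k defaults to 50
(configurable; the reference experiments never printed the winning k).
Distances are taken on the features exactly as provided; scaling choices
live upstream.

Evaluation reports %CCI = 100 (TP+TN)/N on training and test partitions,
their difference delta, and the test confusion matrix.  Configurations are
ranked by test CCI descending, then |delta| ascending, then label — the
"top right corner" of a CCI-vs-delta scatter.

## Synthetic data

The chain generator emits CA-only pseudo-residues (alanines, so they
round-trip through standard PDB I/O) with consecutive spacing exactly
3.8 Å — the canonical trans-peptide CA–CA distance — as a self-avoiding
random walk (excluded-volume radius 3.0 Å between non-consecutive
residues), an ideal α-helix trace (100° twist, 1.5 Å rise, radius solved so
the step is 3.8 Å), or a straight extended chain.  An optional CB
pseudo-sidechain sits 1.5 Å from its CA in a seeded random direction.
These chains exercise geometry, parsing and clique counting, not protein
realism: no Ramachandran constraints, no packing, no secondary-structure
mixtures.

The PPI simulator draws class-conditional count vectors from independent
Poissons with means 6·e^(−i/5) over feature index i (heavy mass at small
counts), forces the last ⌈0.15·dim⌉ features to zero (the structurally
sparse high-index classes), and adds a mean shift δ (default 4) to the
first 10 live features of the positive class; 70/30 train/test split.  A
Poisson model is a testing device — real RCC counts are correlated through
shared cliques — so classifier tests on it demonstrate parameter recovery
(chance-level CCI at δ = 0, monotone CCI in δ, ≥95% at δ = 8 with 200 per
class), not performance on real structures.  All generators are pure
functions of their spec, seed included.

## Problem sizes and numerical choices

Exhaustive oracles bound the sizes used in tests: clique/RCC agreement runs
on 100 random graphs of up to 13 nodes (8192 subsets each), contact-graph
agreement on chains of up to 20 residues, and exact rank-sum agreement on
all group sizes with combined n ≤ 12.  The LP for separability uses the
HiGHS solver; enumeration comparisons use a 1e-9 slack on rank deviations
to absorb float rank sums.  Distance cutoffs are inclusive; KD-tree contact
queries return pairs at exactly the cutoff.

## Known limitations

* One chain = one protein; no inter-chain interface contacts, no symmetry
  mates, first NMR model only.
* Concatenation order sensitivity is surfaced, not resolved.
* The within-size class order and the >6-clique policy are package
  conventions isolated behind `PARTITION_CLASS_TABLE`.
* The LWL reconstruction approximates an unpublished Weka configuration.
* Headline classification rates on the original 3DID/Negatome corpus are
  not reproduced here; they require external data.
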