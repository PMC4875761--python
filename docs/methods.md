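# Methods

## Problem and model

`netbiclust` discovers **modules** in weighted or labeled biological
networks: pairs `(I, J)` of node subsets whose interactions follow a common
value model, not merely a high density of edges.  The network is mapped to
a sparse bipartite adjacency view — a homogeneous network (e.g. a
protein–protein or gene-interaction network) yields one symmetric view in
which both `a_ij` and `a_ji` carry each interaction's value; a network with
`κ` node types yields `C(max(κ,2), 2)` views, one per unordered type pair.
All data structures are lists of `(column, value)` pairs per row node, so
memory stays proportional to the number of interactions `p`, never to
`n·m`.

Five coherency models are supported:

* **dense** — the module's mean interaction weight is significantly high
  (the classical hyperclique target);
* **constant** — `a_ij = k_j + η_ij`: every node of `I` interacts with
  column node `j` at a common expected strength `k_j`, with noise
  `η_ij ∈ [−δ/2, δ/2]`;
* **symmetric** — `a_ij = c_i·k_j + η_ij` with row signs `c_i ∈ {−1,+1}`,
  capturing nodes that activate some partners and repress others within one
  module;
* **plaid** — overlapping modules contribute additively to shared cells;
* **order-preserving** — all rows of `I` induce the same ranking of the
  columns `J` (ties allowed inside co-occurrence groups).

## Mapping: normalization, discretization, itemization

Weighted views are row-centred (zero mean over present interactions only)
and discretized by **overall Gaussian quantiles**: a normal distribution is
fitted to all present values (after clamping |z| > 3 outliers, which
preserves node degrees) and cut points are placed at its `|L|`-quantiles.
The alphabet is signed and symmetric, `{−⌊L/2⌋ … ⌊L/2⌋}` for odd `|L|`
(default 3; the configuration searches {3, 5, 7} jointly when asked), and
the coherency strength is `δ = 1/|L|`.

An element within 25% (relative to the bin width) of a cut point receives
**both adjacent items**; extreme bins only bridge inward, measured against
the nearest interior bin's width since their own width is infinite.  This
multi-item assignment absorbs discretization-boundary noise at the cost of
a modest token inflation (≤ 2× by construction).

Labeled networks skip normalization and discretization; labels map 1:1 to
items.  Node annotations (e.g. ontology terms) append dedicated tokens to
the row's transaction and a trailing group to its sequence.

## Mining

One transaction of `(column, item)` tokens per row node feeds the itemset
and rule miners; one value-ordered column sequence per row (ties grouped)
feeds the sequence miner.  Discretization is optional for sequences; by
default they are built from raw (normalized) values, which yields total
orders per row.

* **Closed itemsets** are mined with a vertical search using
  prefix-preserving closure extensions: each closed set is generated
  exactly once from its canonical parent, projected counts double as
  closure tests, and the root level reads its closures directly off a
  sparse pairwise co-support matrix that is computed once per database and
  reused across all support levels.
* **Association patterns** relax a closed itemset's supporters through
  single-item-consequent rules `Z\{y} ⇒ y` at a confidence threshold
  (default 0.5): a row missing one item may still support the pattern.  At
  confidence 1 this reduces exactly to the closed itemsets.
* **Closed sequences** use prefix growth with two extension steps (join
  the last co-occurrence group, or start a strictly later group).  Rows
  contain each column exactly once, so embeddings are unique and support
  checks reduce to element-index comparisons.  Closedness removes patterns
  with an equally supported super-sequence.

All three miners are exact and are validated against brute-force
enumeration oracles on randomized small databases.  For large networks the
engine bounds each call with a node budget and an emission cap and enables
two lossy prunes that are off by default: skipping branches whose tokens
and supporters sit inside an accepted module (up to 25% stray supporters —
sparse background coincidences attach a few extra rows to any real block),
and skipping branches subsumed by a pattern already emitted in the same
call.  This realizes the similarity computation pushed into the mining
step; within the caps and before any module is accepted the searches are
exhaustive.

Declarative constraints on the pattern `φ_B` are supported in the
classical taxonomy: succinct `remove(S)` rewrites the database before
mining; anti-monotone predicates are pushed into candidate growth (pruning
on both the candidate and its closure, which provably equals post-hoc
filtering); monotone and convertible predicates (`countVal ≥ k`,
`avg ≤ c`, extrema, required items) are checked post hoc.

## The support loop

Mining runs at a decreasing support threshold: θ starts at 80% of the rows
and decays by 10% multiplicatively.  Levels above the largest cross-column
pairwise co-support cannot contain any multi-column pattern and are
skipped outright.  The loop stops when

1. 50 dissimilar modules have been found, or
2. the accepted modules cover ≥ 10% of the present interactions, or
3. the absolute support would fall below a **spurious-pattern floor**, or
4. two consecutive levels add no new dissimilar module (patience).

The floor is `μ + 5√μ`, where `μ` is the expected co-support of two
unrelated columns under the network's density (for the order-preserving
search, a degree-aware version using the 90th presence percentile, since
ordered co-support scales with column degrees).  Below this level the
number of background patterns grows combinatorially while none of them can
be distinguished from chance; the two stated stop rules alone do not
terminate at bounded cost.

Same-column token pairs (the two adjacent items of one boundary element)
co-occur strongly but can never span a two-column module; excluding them
from the co-support prefilter lets the search skip almost every background
token at every level.

## Noise tolerance: extension, reduction, merging

Each mined pattern becomes a candidate module (`I` = supporting rows, `J` =
pattern columns) and is then **extended**: rows whose mismatch against the
pattern is ≤ 0.2 are added (for symmetric modules each candidate row enters
with the sign that matches best — greedy per-row sign correction), then
columns supported by enough member rows are added with their majority item.
Because a small seed's supporters include background rows, the first column
pass uses a relaxed majority vote (55%) and later passes the strict noise
bound; the spurious rows drop out once the pattern has grown.  A
**reduction** pass then removes rows and columns exceeding the bound, so a
module converges to the maximal coherent block around the seed.  Modules
whose interaction-cell Jaccard similarity reaches 80% are merged
(descending-similarity fixpoint), modules similar (≥ 70%) to a strictly
larger module are filtered, and modules without statistical significance
are dropped.

Extension and reduction are enabled by default.  This deviates from the
recommendation to run without them: exact closed-pattern mining cannot
recover a module once ~10% of its cells are perturbed (full-pattern support
decays as `0.9^|J|`), so the bounded extension is what carries the
pipeline's noise tolerance; the merging and multi-item mechanisms alone do
not suffice at that noise level.

For homogeneous networks the symmetric fill stores each interaction twice,
so every module also surfaces as partial **mirrors** (column slices with
swapped roles).  Mirrors stay in the working pool — their patterns suppress
redundant re-mining — but only mirror-deduplicated modules are counted as
dissimilar and reported.

**Plaid** modules start from the noise-tolerant constant search; cells
deviating inside a module are then re-tested as the sum of the expected
values (discretization-bin centres) of all modules covering them, using
each module's relaxed candidate pattern so that a column trimmed from two
overlapping modules can still be attributed.  Cells additive within half a
bin width are marked explained and count as coherent in further extension
rounds; the loop runs to a fixpoint (cap 10 iterations).

**Order-preserving** search on large networks first groups columns into
candidate blocks: exact directed ordered-pair counts are accumulated with
one pass over the sequence database, pairs above the current support
threshold define a column graph, and its connected components bound where
order-preserving structure can live.  Exact closed-sequence mining runs
inside each block (components inside an accepted module are skipped).
Extension estimates a consensus column order from the mean normalized
ranks of the supporting rows and coarsens it into co-occurrence groups of
~4 columns — the n/4-rank convention — so that value jitter and small
consensus errors do not break otherwise coherent rows; rows are scored by
the longest non-decreasing subsequence of group indices.

## Statistical significance

A module's p-value is the Bonferroni-corrected binomial tail
`P(X ≥ |I|)` with `X ~ Binomial(n, q)`, under a null of independent rows
with empirical item marginals: `q` is the product over `J` of the observed
frequency of the expected item (multi-item elements counted once), with
the symmetric model allowing either sign and the order-preserving model
using presence frequencies times the fraction of orderings the pattern
admits.  The correction factor counts the candidate patterns the miners
actually examined (search-tree nodes accumulated over the support loop),
not only the closed patterns that were emitted — with emission-only
counting, borderline random two-column blocks on a pure-background network
can slip past the threshold.  Modules with corrected `p ≥ 0.01` are
dropped.  This null ignores the
network's degree structure; a degree-preserving rewiring null would be the
natural refinement and is left as a hook.

## Synthetic benchmark

The generator plants `k` modules in an `n`-node homogeneous network at a
target density (defaults per size: 200 nodes/5 modules/[20,30] nodes per
module, 500/10/[30,40], 1000/15/[40,50], 2000/20/[50,70],
10000/30/[100,140], all at 10% density).  A module's total node count is
drawn uniformly, scaled by coherency (1.2 dense, 1.0 constant, 1.2
symmetric, 1.1 plaid, 1.5 order-preserving, keeping harder coherencies
statistically significant), and split evenly into disjoint row and column
subsets; a shape-imbalance parameter skews the split.  Cells receive the
pattern value — a bin centre of the standard-normal quantile alphabet —
plus Uniform(−δ/2, δ/2) jitter; order-preserving modules spread their base
values over the central 90% of the normal range with jitter a third of the
spacing.  Expected strengths are drawn from the **non-neutral** symbols
only: a near-zero weight in a sparse network denotes the absence of an
association, so neutral-symbol "modules" would be both biologically
meaningless and statistically indistinguishable from background.  Noise
replaces a fraction of module cells with background draws; a missing
fraction deletes them; background edges are then added until the edge
count meets `density·n²/2`.  Under this convention the expected fraction
of interactions inside modules reproduces the benchmark design's printed
values (≈19.8%, 12.3%, 7.6%, 4.5%, 1.1% for the five sizes; the printed
values are the mean-size arithmetic and differ from the exact expectation
by at most ~0.3 points at the smallest size).

What the generator does **not** emulate: scale-free degree distributions,
transitivity/clustering of real interaction networks, correlated
measurement error, and confidence-score calibration artifacts.  Passing
recovery tests therefore demonstrates correctness of the method under the
declared value models and noise processes, not performance on any real
interactome.

Recovered solutions are scored with the match score

    MS(B, H) = 1/|B| Σ_{(I1,J1)∈B} max_{(I2,J2)∈H} √( |I1∩I2|/|I1∪I2| · |J1∩J2|/|J1∪J2| ),

evaluated in both directions; for homogeneous networks each comparison
also tries the transposed assignment and keeps the larger value.

## Problem sizes and defaults used in the tests

The test suite validates miners against brute-force enumeration on ≥ 1000
random databases of ≤ 8 rows × ≤ 6 items (sequences ≤ 4 tokens, where the
ordered-partition oracle stays cheap), measures planted-interaction
fractions over 2000/30/30 instances for the 200/1000/2000-node settings
(the smallest setting's per-instance spread of ~2.2 points requires the
larger sample for a 0.5-point comparison), and measures recovery on
2000-node networks with 10% noise over 10 instances per coherency model
with discretization alphabet {3} (matching the generator's alphabet).  The
robustness contrast plants 10% missing interactions in dense modules and
compares the default configuration against one with multi-items, merging
and extension disabled.

## Known limitations

* The engine's mining budgets (`node_budget`, `max_patterns`) make the
  per-level searches support-greedy beams when exhausted; extension,
  merging and the level cascade compensate in practice, but pathological
  inputs can hide patterns below the caps.
* The symmetric variant of the order-preserving model (sign-corrected
  sequence mining) is not implemented.
* Significance uses row-independence with empirical marginals, not a
  degree-preserving null.
* Dynamic distribution fitting is reduced to the single Gaussian scheme
  (the cut-point computation is a pluggable hook).
* Heterogeneous networks are decomposed and mined per view; cross-view
  module integration is left to the caller.
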