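# Methods

This note records the statistical model behind `deltarank`, the numerical
conventions the implementation commits to, what the synthetic generator
does and does not emulate, and the design choices made where more than one
defensible option existed.

## The delta rank transform

For a genes × cells expression matrix with *m* genes and *n* cells, each
cell's values are converted to ranks 1..m (smallest value → rank 1). For
every edge *(g_i, g_j)* of a background gene-interaction network, the raw
delta rank in cell *c* is

    Δ(e, c) = r_i,c − r_j,c ∈ [−(m−1), m−1].

The edges × cells matrix of Δ values, z-scored within each cell (column),
is the normalized DRM. The transform rests on one modelling assumption:
that within-cell orderings of interacting gene pairs are a stable
cell-type property, while absolute expression values are contaminated by
cell- and batch-specific monotone distortions (library size, capture
efficiency, platform response). Under that assumption the raw DRM is an
exact invariant: any strictly increasing per-cell transform of the
expression values leaves every rank, hence every Δ, bitwise unchanged.
The property tests assert this for log1p, affine and power distortions
with per-cell parameters.

Useful algebraic consequences, also asserted in tests: flipping an edge's
stored orientation negates its row exactly; for any edge triangle
(a,b),(b,c),(c,a) the three raw rows telescope to the zero vector; each
rank column sums to m(m+1)/2.

### Numerical conventions

- **Ties** are ranked by the average of the spanned ranks ("fractional"
  ranks, via `scipy.stats.rankdata`). In zero-inflated scRNA-seq columns
  this is the only rule under which two co-zero genes — which carry no
  ordering information — get Δ = 0 exactly. `min`, `max`, `dense` and
  `ordinal` are available as options. All *m* genes are ranked, including
  all-zero ones, which share the tied bottom block.
- **Z-scoring** uses the sample standard deviation (divisor l−1). A
  zero-variance column maps to all zeros; a DRM with a single edge cannot
  be z-scored and is rejected.
- **Edge orientation.** Edges are undirected for uniqueness but Δ's sign
  depends on orientation, so the first orientation encountered in the
  source file is canonical and is preserved by cleaning, restriction and
  serialization (`GENEA|GENEB`). The cleaning report (self-loops,
  duplicates, dropped edges) is carried on the network object and written
  into output headers.
- **Analysis layer.** Feature selection and marker testing operate on the
  normalized DRM; cell-specific-network significance uses raw Δ. Within a
  cell, z-scoring is an affine map, so empirical p-values computed on
  either layer would be identical — raw is used so the closed-form null
  (below) applies directly.

## Feature selection

Rows (edges or genes) are ranked by sample variance across cells,
descending, ties broken by original row order; the default selection size
is k = 500. The coefficient of variation CV = sd / |mean| is provided for
comparing dispersion of edge features against gene features; the absolute
value in the denominator is needed because normalized DRM rows can have
negative means, and rows with |mean| < 1e-12 are flagged with an infinite
sentinel and excluded from CV rankings (the ratio no longer measures
dispersion there). Which layer the CV comparison uses is configurable;
the default is the normalized layer, consistent with the analysis layer.

## Marker edges

For each cell type *t*, every edge is tested one-vs-rest with a two-sided
unequal-variance (Welch) t-test on the normalized DRM, p-values are
BH-adjusted within the type's family of *l* tests, edges with q < 0.01
are ordered by decreasing

    FD(e, t) = | mean Δ in type t − mean Δ outside t |

(ties by edge order), and the top k per type are combined. An edge
significant for several types keeps all its per-type rows but counts once
in the combined unique-edge set. Edges with zero variance in both groups
get t = 0, p = 1 unconditionally: with no within-group spread the Welch
statistic is undefined and such an edge provides no testable evidence. A
type with no significant edge yields a warning, not an error. Overlap of
a marker-derived gene set with a known marker list is scored by the
upper-tail hypergeometric probability of at least the observed overlap.

## Cell-specific networks

For one cell, the null distribution of Δ is estimated by Monte Carlo:
each of N draws (default 10,000) is r_a − r_b for an ordered pair of two
distinct positions sampled uniformly from the cell's own rank vector —
equivalent to shuffling gene labels and reading a fixed edge, and valid
with ties present. Under label shuffling all edges share the same null,
so one null per cell serves every edge. The two-sided empirical p-value
uses the add-one estimator

    p = (#{ |sample| ≥ |Δ_obs| } + 1) / (N + 1),

which never returns zero; edges with p < α (default 0.05, uncorrected by
design — the threshold is a per-cell screening rule, not an inference
family) form the cell-specific network. For tie-free ranks the null has
the closed form P(Δ = d) = (m − |d|)/(m(m−1)) on d ∈ ±{1..m−1}, which the
test suite uses as an independent oracle for the sampler (chi-square
goodness of fit) and for p-value calibration (≈5% of random edges flagged
at α = 0.05). Note that a finite iid sample of N = 10,000 draws over the
98-point support at m = 50 carries an irreducible expected total-variation
error of ≈ 0.04 relative to the exact pmf; the goodness-of-fit test, not
a raw TV threshold, is therefore the meaningful correctness check at this
sample size.

Cell-type networks aggregate raw Δ by its mean over the cells of a type;
common-pattern summaries report, for each background edge incident to a
chosen gene, the fraction of cells whose CSN contains it.

## Clustering evaluation

Cells are clustered in feature space with standard backends (k-means with
10 restarts, Ward-linkage hierarchical on Euclidean distances, spectral
with RBF affinity), all deterministic under a fixed seed. Partitions are
scored with ARI (pair-counting, chance-corrected), NMI normalized by the
arithmetic mean of the two label entropies (defined as 1 when both
partitions are single-cluster), and purity (majority-class fraction;
all-singleton predictions trivially score 1 — a known inflation the index
carries by construction). ARI and NMI are checked exhaustively against
definitional implementations over all pairs of the 203 set partitions of
six items.

## The synthetic generator

The generator emulates the one data property the method depends on:
cell-type identity expressed through within-cell orderings rather than
through expression levels.

- Baseline per-gene levels are lognormal (log-levels N(1, 1)), shared by
  all cells — heavy-tailed positive values resembling normalized
  expression.
- Each type owns a disjoint set of planted gene pairs (each gene in at
  most one pair). A pair's two levels are c·e^(±effect/2) around a center
  c drawn from the well-expressed bulk (log-center N(1.25, 0.25)) — as
  real marker genes tend to be — and are swapped in the owning type only.
  The `effect` parameter (default 1.0) is the log-scale expression gap;
  at effect = 0 the swap is a no-op and the generator is an exact null,
  and the planted between-type Δ gap grows monotonically with it (both
  tested).
- Every cell receives multiplicative lognormal gene noise (log-sd 0.25;
  the probability that noise flips a planted ordering is
  Φ(−effect/(0.25·√2)) ≈ 0.2% at the default effect) and a per-cell scale
  factor (log-sd 0.3) standing in for library size.
- Dropout zeroes entries with probability proportional to
  exp(−x / cell mean), rescaled so the realized zero fraction matches
  `dropout_rate` (default 0.3). Expression-dependent zeros are the
  empirically correct model for scRNA-seq and are essential here: uniform
  zeroing (available via a flag) at high rates destroys ordering
  information symmetrically — at rate 0.6 only ~16% of cells retain both
  endpoints of a pair and no effect size makes planted edges reliably
  significant — whereas expression-dependent zeros concentrate in the
  uninformative low end, as they do in real data.
- The background network contains all planted edges plus random filler
  edges, shuffled; filler edges never join two planted genes, since an
  accidental edge between two same-type swapped genes would be exactly as
  differential as a planted edge and would make the planted set an
  ill-defined ground truth.

What the generator does **not** emulate: UMI counting noise, library-size
distributions, batch effects beyond monotone distortions, correlated gene
modules, doublets, or biologically structured networks (filler edges are
random). Passing recovery tests therefore demonstrate that the pipeline
extracts planted ordering signal under noise and realistic dropout — not
that it will reach any particular accuracy on real tissue data.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 200–600
genes, 90–210 cells, 400–800 edges, 10,000-draw nulls, chosen so the full
pipeline (simulation → DRM → markers → clustering → scoring) executes in
seconds to a few minutes on one CPU. Every stochastic step takes an
explicit seed; the CLI derives per-stage substreams from the run seed, so
identical configurations reproduce byte-identical outputs.

## Known limitations

- A species without a prior interaction network cannot be analyzed; the
  transform is only defined over supplied edges.
- Heavy tie blocks (extreme dropout) shrink the effective support of Δ
  and the empirical null; significance calls for near-all-zero cells are
  conservative (few or no edges pass).
- The CSN p-values are screening statistics, not family-wise inferences.
- Purity is reported for comparability but is inflated by fine
  partitions; read it next to ARI/NMI.
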