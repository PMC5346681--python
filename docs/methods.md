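# Methods

## Networks and cleaning

Interactomes are undirected simple graphs over opaque, case-sensitive gene
identifiers (typically Entrez IDs; no validation or ID mapping is
performed — inputs are assumed pre-mapped). Loading an edge list drops
self-loops and collapses redundant records, including the same pair in
opposite orientation; counts of dropped records are logged. Columns beyond
the first two are ignored, since the analysis treats all networks as
unweighted. By default the gene universe is the union of edge endpoints; an
optional node list declares isolated genes explicitly. The writer emits
lexicographically canonicalized, sorted pairs so cleaned files diff
reproducibly, and write→load is an identity on cleaned networks.

## Centrality

Degree is the number of distinct partners. Betweenness for gene *i* is the
unnormalized pair-fraction sum BC_i = Σ_{j<k, j≠i≠k} g_jk(i)/g_jk; pairs in
different components contribute nothing. It is computed by Brandes'
dependency accumulation (one BFS per source on the unweighted graph,
summing over sources and halving to count unordered pairs once), which is
exact; the test suite verifies it against a brute-force enumeration of all
shortest paths on hundreds of small random graphs and against an
independent library implementation. No normalization is applied: any
constant factor cancels in within-network rankings, and the unnormalized
form is the plain reading of the defining sum. Disconnected networks are
handled without restriction to a largest component.

Rankings sort by descending score. Ties are broken lexicographically by
default — arbitrary but fully reproducible — or by a seeded random key when
a tie-neutral ordering is wanted; in either case a ranking is a pure
function of (scores, tie rule, seed).

## Recovery evaluation

Positives are the gold-standard genes present in the network; all remaining
network genes are negatives. At threshold fraction *f* the top ⌊f·N⌋ genes
are predicted positive (the floor rule affects at most one gene; products
are rounded at 1e-9 before flooring so binary float representation cannot
lose a gene). Recall, accuracy and specificity follow the standard
confusion-table quotients; a zero denominator yields an undefined (NaN)
value, never zero. The default sweep is 1% steps from 0 to 100%.

Recall is within-network by default (denominator = positives in the
network). Because networks cover different gene subsets, an optional
`total_positives` denominator (e.g. the full gold-standard count) makes
recall comparable across networks on a common scale; within-network is the
default as it matches the positives/negatives definition above.

## Permutation enrichment

The null randomizes the gene *ranking*, not the edges: gene order is
permuted uniformly, and recovery in the top ⌊f·N⌋ is recorded per
permutation (defaults f = 0.10, n_perm = 1000). Fold enrichment is the
observed recovered proportion divided by the null mean proportion. Because
a random ranking makes the top block a simple random sample, null recovery
is hypergeometric with mean ⌊f·N⌋·|P|/N — the Monte-Carlo mean is checked
against this closed form. The empirical p-value uses the add-one estimator
(1 + r)/(n_perm + 1), so p is never zero and its floor at the default
settings is 1/1001 ≈ 0.001. Every result records its seed.

## Robustness to incompleteness

Edge down-sampling retains a uniform random subset of |E| − round(f·|E|)
edges; the gene universe is unchanged, so genes stripped of all edges stay
in the ranking with degree 0 (ordered by the tie rule) and confusion-table
denominators remain comparable across removal fractions. Re-ranking uses
degree (the down-sampling question is posed for the degree ranking; other
metrics propagate through the same machinery if needed). Defaults: removal
grid 0–0.9 in 0.1 steps, 10 replicates per fraction, evaluation cutoff
0.10. Each (fraction, replicate) cell derives its seed deterministically
from (run seed, fraction index, replicate index), so profiles are
byte-identical across reruns.

## Cross-network comparison

Relative rank = rank/N per network, in (0, 1], NaN where a gene is absent.
The top-k overlap (k defaults to 100) reports how many focal top genes
occur in at least one other network and which of them also sit at relative
rank ≤ `low_rank_cut` (default 0.10) in at least one other network; the
threshold behind "also highly ranked elsewhere" is a free parameter, so
every report carries the cut used.

## Mutation frequencies and the rank-group test

Only the minimal MAF dialect is parsed: Hugo_Symbol (or Entrez_Gene_Id),
Tumor_Sample_Barcode, Variant_Classification, plus an optional Cancer_Type
column or a per-file label. By default every record counts as a mutation;
an exclude-silent switch is provided since variant-class conventions vary.
Frequency is mutated samples / total samples per cancer, with per-sample
deduplication (multiple records of a gene in one sample count once). Cohort
sizes should be supplied explicitly — inferring them from distinct barcodes
undercounts whenever some samples carry no mutation, and the generator
therefore returns true cohort sizes beside its records.

Top-ranked vs bottom-ranked gene groups are compared by the Wilcoxon
rank-sum (Mann–Whitney) test on their frequency vectors, one-sided
(top > bottom) by default because the hypothesis is directional; two-sided
is available. The exact null distribution is used when the combined sample
size is ≤ 20 with no ties, otherwise the normal approximation with tie
correction. If every frequency is identical the comparison is degenerate
and reported as p = 1 with a note. Genes absent from the table count as
frequency 0.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

- **Network**: Barabási–Albert preferential attachment (default), m = 3 new
  edges per node — mean degree ≈ 6, comparable to the density of published
  human interactome maps — giving exactly (n−m)·m edges; or a configuration
  model with zeta-distributed degrees (exponent γ, default 2.5, clipped to
  [min_degree, n−1], simplified afterwards, so realized degrees are
  approximate).
- **Positives**: n_positives genes (default 50 of 1,000) sampled without
  replacement with probability ∝ (degree+1)^β. β is the single effect-size
  knob for the hub hypothesis: β = 0 plants uniformly (nothing for a
  centrality ranking to find), the reference condition β = 2 concentrates
  positives on hubs strongly enough that degree ranking recovers roughly
  half of them in the top decile (fold enrichment ≈ 5). The +1 keeps
  isolated genes sampleable.
- **Mutations**: per cancer label (default three labels, 200 samples each),
  each (gene, sample) pair mutates independently — 1% baseline rate, 20%
  for positives — emitted as minimal-dialect MAF.

What the generator does **not** emulate: assay-specific artifacts (bait/prey
sampling, spoke expansion), correlated mutations, mutational signatures, or
literature bias in network ascertainment. Passing tests therefore
demonstrate the pipeline's statistical correctness and its behavior under
the hub-enrichment model, not the biological performance of any real
interactome.

## Problem sizes and determinism

Tests and the acceptance script run at 1,000 genes, 1,000 permutations,
10 robustness replicates, and 100–1,000 simulation replicates for
calibration checks — sizes at which Monte-Carlo tolerances (3 standard
errors unless stated) are tight enough to be meaningful while the whole
suite completes in well under a minute of compute per stage. All
randomness flows through numpy `SeedSequence`-derived generators keyed by
an explicit run seed, so every artifact is bit-reproducible.

Known limitations: betweenness is exact but O(n·m), so very large networks
are slow in pure Python; the loader holds adjacency in memory; the
permutation null randomizes rankings only (degree-preserving edge-rewiring
nulls are deliberately out of scope); and GO/pathway enrichment,
literature co-occurrence and ID mapping are outside the package's remit.
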