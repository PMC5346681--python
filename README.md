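# ppibench

Benchmarking protein–protein interaction (PPI) networks for
centrality-based cancer gene prioritization.

## The problem

Hub genes in interactome networks are disproportionately likely to be
disease-associated, and many prioritization pipelines simply rank genes by
network centrality. But published human interactome maps differ widely in
size, ascertainment and bias, and it is not obvious which map — a curated
literature network, a computationally predicted one, or an unbiased
systematic screen — gives the best context for finding cancer genes.
`ppibench` provides the comparative machinery to answer that question for
any collection of edge-list networks and any gold-standard gene list, plus
a synthetic-data generator so the entire pipeline is testable at desk scale
without external downloads.

## What it computes

For a network *G* = (*V*, *E*) over gene identifiers:

- **Centrality rankings.** Degree *k_i* (distinct partners) and unnormalized
  betweenness *BC_i* = Σ_{j<k} *g_jk(i)* / *g_jk*, where *g_jk* counts
  shortest *j*–*k* paths and *g_jk(i)* those passing through *i* (Brandes
  accumulation, exact for unweighted graphs). Ties break lexicographically
  by default, or by a seeded random key.
- **Gold-standard recovery.** With positives *P* ⊆ *V* (a gold-standard
  list intersected with the network) and the top ⌊*f·N*⌋ ranked genes
  called positive: recall = TP/(TP+FN), accuracy = (TP+TN)/N,
  specificity = TN/(TN+FP), swept over a threshold grid.
- **Permutation fold enrichment.** Gene order is randomized *n* times
  (default 1,000); fold enrichment = observed recovered proportion in the
  top fraction ÷ mean proportion under the null, with empirical
  *p* = (1 + #{null ≥ observed}) / (*n* + 1).
- **Robustness to incompleteness.** A stated fraction of edges is removed
  uniformly at random, genes are re-ranked by degree on the remainder
  (universe fixed, so denominators are comparable), and the metrics are
  recomputed per replicate.
- **Cross-network comparison.** Relative rank = rank / *N* per network;
  top-*k* overlap counts which focal top genes appear — and which are also
  highly ranked — in other networks.
- **Mutation frequencies.** From MAF-like tables, freq(*g*, *c*) = mutated
  samples / total samples per cancer; top-*k* vs bottom-*k* ranked genes are
  compared by a one-sided Wilcoxon rank-sum test.

The synthetic generator produces scale-free-ish networks (preferential
attachment or a power-law configuration model), plants a positive gene set
with selection probability ∝ (degree+1)^β — β is the hub-bias effect size —
and emits Bernoulli mutation tables with an elevated per-sample rate for a
designated gene subset.

## Worked example

Generate a synthetic interactome with hub-planted positives and ask whether
degree ranking recovers them:

```
$ ppibench --seed 7 --out-dir demo simulate --n-genes 1000 --n-positives 50
wrote network (1000 genes, 2991 edges), 50 positives, 11709 mutation records to demo

$ ppibench --seed 7 --out-dir demo enrich --network demo/network.tsv \
      --positives demo/positives.txt
{
  "metric": "degree",
  "fraction": 0.1,
  "observed_recovery": 28,
  "observed_proportion": 0.56,
  "null_mean_proportion": 0.09976000000000002,
  "fold_enrichment": 5.613472333600641,
  "p_empirical": 0.000999000999000999,
  "n_permutations": 1000,
  "seed": 7
}
```

The top 10% of the degree ranking contains 28 of the 50 planted positives
(56%), while random rankings recover about 10% — a 5.6-fold enrichment whose
empirical p-value is at the floor of 1/1001, i.e. no random ranking in
1,000 permutations did as well. The same library calls are available in
Python (`generate_network`, `plant_positives`, `rank_genes`,
`permutation_null`, …), and `ppibench run-all --config run.yaml` executes
every stage (evaluation curves, enrichment, robustness, cross-network
tables, mutation tests) from one declarative config.

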