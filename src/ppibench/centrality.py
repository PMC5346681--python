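"""Topological centrality scores and deterministic gene rankings.

Two centralities are supported, reflecting how hub genes are prioritized in
interactome analyses:

* **degree** — the number of distinct interaction partners of a gene;
* **betweenness** — for gene *i*, the sum over unordered gene pairs
  ``{j, k}`` (``j != i != k``) of ``g_jk(i) / g_jk``, where ``g_jk`` counts
  shortest paths between *j* and *k* and ``g_jk(i)`` those passing through
  *i*.  Values are **unnormalized** pair-fraction sums; pairs in different
  connected components contribute nothing.  Any constant normalization would
  leave the within-network ranking unchanged.

Betweenness is computed by Brandes' dependency-accumulation algorithm on
unweighted graphs (one BFS per source, O(nm) total), which evaluates the
pair-fraction formula exactly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .network_io import InteractionNetwork

__all__ = [
    "CentralityScores",
    "GeneRanking",
    "degree_scores",
    "betweenness_scores",
    "rank_genes",
    "write_ranking",
]

TIE_RULES = ("lexicographic", "random_seeded")


@dataclass(frozen=True)
class CentralityScores:
    """A metric name plus a score for every gene in the network."""

    metric: str
    scores: Mapping[str, float]


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered best-first by a centrality score.

    ``order`` is a permutation of the network's genes with non-increasing
    scores; within a tied block the tie rule fully determines the order, so
    a ranking is reproducible from (scores, tie_rule, seed).
    """

    metric: str
    order: tuple[str, ...]
    scores: Mapping[str, float]
    tie_rule: str = "lexicographic"
    seed: int | None = None
    _rank: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_rank", {g: i + 1 for i, g in enumerate(self.order)}
        )

    @property
    def n_genes(self) -> int:
        return len(self.order)

    def rank_of(self, gene: str) -> int:
        """1-based rank (1 = most central)."""
        return self._rank[gene]

    def relative_rank_of(self, gene: str) -> float:
        """Rank divided by the total number of genes; in (0, 1]."""
        return self._rank[gene] / len(self.order)

    def top(self, k: int) -> tuple[str, ...]:
        return self.order[:k]


def degree_scores(network: InteractionNetwork) -> CentralityScores:
    """Number of distinct interaction partners of each gene."""
    return CentralityScores(
        metric="degree",
        scores={g: network.degree(g) for g in network.genes},
    )


def betweenness_scores(network: InteractionNetwork) -> CentralityScores:
    """Unnormalized betweenness via Brandes accumulation.

    For each source ``s`` a BFS computes shortest-path counts ``sigma`` and
    predecessor lists; back-propagation accumulates the dependency
    ``delta[v] = sum_{w: v in pred(w)} sigma[v]/sigma[w] * (1 + delta[w])``.
    Summing over sources counts every unordered pair twice, so the total is
    halved.
    """
    adj = network.adjacency()
    bc: dict[str, float] = {g: 0.0 for g in network.genes}
    for s in network.genes:
        # single-source shortest paths (unweighted)
        pred: dict[str, list[str]] = {v: [] for v in adj}
        sigma: dict[str, float] = {v: 0.0 for v in adj}
        dist: dict[str, int] = {}
        sigma[s] = 1.0
        dist[s] = 0
        stack: list[str] = []
        queue: deque[str] = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta: dict[str, float] = {v: 0.0 for v in adj}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return CentralityScores(
        metric="betweenness", scores={g: v / 2.0 for g, v in bc.items()}
    )


def rank_genes(
    scores: CentralityScores,
    tie_rule: str = "lexicographic",
    seed: int | None = None,
) -> GeneRanking:
    """Order genes by descending score with a deterministic tie rule.

    ``lexicographic`` breaks ties alphabetically; ``random_seeded`` breaks
    them by a seeded random key, identical across runs for the same seed.
    """
    if tie_rule not in TIE_RULES:
        raise ValueError(
            f"unknown tie_rule {tie_rule!r}; expected one of {TIE_RULES}"
        )
    genes = sorted(scores.scores)
    if tie_rule == "random_seeded":
        if seed is None:
            raise ValueError("tie_rule='random_seeded' requires a seed")
        rng = np.random.default_rng(seed)
        key = dict(zip(genes, rng.permutation(len(genes))))
        order = sorted(genes, key=lambda g: (-scores.scores[g], key[g]))
    else:
        order = sorted(genes, key=lambda g: (-scores.scores[g], g))
    return GeneRanking(
        metric=scores.metric,
        order=tuple(order),
        scores=dict(scores.scores),
        tie_rule=tie_rule,
        seed=seed,
    )


def write_ranking(ranking: GeneRanking, path: str | Path) -> None:
    """TSV: gene, score, rank (1-based, best = 1)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene\tscore\trank\n")
        for i, g in enumerate(ranking.order, start=1):
            fh.write(f"{g}\t{ranking.scores[g]:g}\t{i}\n")
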