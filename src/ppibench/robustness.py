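"""Down-sampling analysis: prediction stability under network incompleteness.

Interactome maps are incomplete, so a useful question is whether
centrality-based gene prioritization survives missing interactions.  The
analysis removes a stated fraction of edges uniformly at random, re-ranks
genes by degree in the remaining network, and re-evaluates recall, accuracy
and specificity at a fixed threshold fraction.  The gene universe is held
constant — genes whose last edge is removed stay in the ranking with degree
zero — so confusion-table denominators are comparable across removal
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .centrality import degree_scores, rank_genes
from .evaluation import confusion_at_fraction, metrics
from .network_io import GeneSet, InteractionNetwork

__all__ = ["RobustnessProfile", "downsample_edges", "robustness_profile"]


def downsample_edges(
    network: InteractionNetwork, fraction_removed: float, seed: int
) -> InteractionNetwork:
    """Retain a uniformly random subset of ``|E| - round(f*|E|)`` edges.

    The gene universe is unchanged; genes may become isolated (degree 0).
    """
    if not 0.0 <= fraction_removed <= 1.0:
        raise ValueError("fraction_removed must be in [0, 1]")
    edges = sorted(network.edges)
    n_remove = round(fraction_removed * len(edges))
    n_keep = len(edges) - n_remove
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(edges), size=n_keep, replace=False)
    kept = [edges[i] for i in keep_idx]
    return InteractionNetwork(kept, genes=network.genes)


@dataclass(frozen=True)
class RobustnessProfile:
    """Per-(removal fraction, replicate) metrics at a fixed cutoff.

    ``frame`` columns: fraction_removed, replicate, n_edges, recall,
    accuracy, specificity.
    """

    frame: pd.DataFrame
    eval_fraction: float
    replicates: int
    fractions_removed: tuple[float, ...]
    seed: int

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric per removal fraction."""
        return (
            self.frame.groupby("fraction_removed")[
                ["recall", "accuracy", "specificity"]
            ]
            .agg(["mean", "std"])
            .reset_index()
        )


def robustness_profile(
    network: InteractionNetwork,
    positives: GeneSet,
    fractions_removed: Sequence[float] = tuple(np.round(np.arange(0, 0.91, 0.1), 2)),
    replicates: int = 10,
    eval_fraction: float = 0.10,
    metric_source: str = "degree",
    seed: int = 0,
) -> RobustnessProfile:
    """Down-sample, re-rank by degree, re-evaluate — for every
    (fraction, replicate) pair, each seeded deterministically from
    ``(seed, fraction index, replicate index)``.
    """
    if metric_source != "degree":
        raise ValueError(
            f"metric_source {metric_source!r} unsupported; only 'degree'"
        )
    if not positives.ids <= network.genes:
        raise ValueError("positives must be a subset of the network's genes")
    rows = []
    for fi, frac in enumerate(fractions_removed):
        for rep in range(replicates):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(fi, rep))
            sub_seed = int(child.generate_state(1)[0])
            sub = downsample_edges(network, frac, seed=sub_seed)
            ranking = rank_genes(degree_scores(sub))
            c = confusion_at_fraction(ranking, positives, eval_fraction)
            m = metrics(c)
            rows.append(
                {
                    "fraction_removed": frac,
                    "replicate": rep,
                    "n_edges": sub.n_edges,
                    "recall": m.recall,
                    "accuracy": m.accuracy,
                    "specificity": m.specificity,
                }
            )
    return RobustnessProfile(
        frame=pd.DataFrame(rows),
        eval_fraction=eval_fraction,
        replicates=replicates,
        fractions_removed=tuple(fractions_removed),
        seed=seed,
    )


def write_profile(profile: RobustnessProfile, path: str | Path) -> None:
    profile.frame.to_csv(path, sep="\t", index=False)
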