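"""Comparing gene rankings across interactome networks.

Different maps cover different gene subsets, so raw ranks are not
comparable.  The *relative rank* — a gene's rank divided by the total number
of genes in that network, in (0, 1], smaller = more central — puts networks
of different sizes on one scale.  The top-k overlap summary asks how many of
a focal network's top-ranked genes appear in other networks at all, and how
many are also highly ranked (relative rank at or below a stated cut) in at
least one of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .centrality import GeneRanking

__all__ = ["relative_ranks", "top_k_overlap", "OverlapSummary"]


def relative_ranks(
    rankings: Mapping[str, GeneRanking], genes: Sequence[str]
) -> pd.DataFrame:
    """Genes x networks table of relative ranks; NaN where a gene is absent.

    A present gene's value is ``rank / N_network`` and is never 0; the
    last-ranked gene gets exactly 1.0.
    """
    if not rankings:
        raise ValueError("rankings must be nonempty")
    data = {}
    for label, ranking in rankings.items():
        universe = set(ranking.order)
        data[label] = [
            ranking.relative_rank_of(g) if g in universe else float("nan")
            for g in genes
        ]
    return pd.DataFrame(data, index=list(genes))


@dataclass(frozen=True)
class OverlapSummary:
    """Top-k genes of a focal ranking versus other networks.

    ``shared_any`` counts top genes present in at least one other network;
    ``low_ranked_elsewhere`` lists those whose relative rank is <= the cut in
    at least one other network; ``not_low_elsewhere`` is its complement
    within the shared genes.  Reported results always carry the cut used.
    """

    top_genes: tuple[str, ...]
    shared_any: int
    low_ranked_elsewhere: tuple[str, ...]
    not_low_elsewhere: tuple[str, ...]
    k: int
    low_rank_cut: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "k": self.k,
                "low_rank_cut": self.low_rank_cut,
                "top_genes": list(self.top_genes),
                "shared_any": self.shared_any,
                "low_ranked_elsewhere": list(self.low_ranked_elsewhere),
                "not_low_elsewhere": list(self.not_low_elsewhere),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def top_k_overlap(
    focal: GeneRanking,
    others: Mapping[str, GeneRanking],
    k: int = 100,
    low_rank_cut: float = 0.10,
) -> OverlapSummary:
    """Overlap of the focal top-k with other networks' gene sets and ranks."""
    if k > focal.n_genes:
        raise ValueError(
            f"k={k} exceeds the focal network's {focal.n_genes} genes"
        )
    top = focal.top(k)
    other_universes = {label: set(r.order) for label, r in others.items()}
    shared = [
        g for g in top if any(g in u for u in other_universes.values())
    ]
    low_elsewhere = []
    for g in top:
        for label, r in others.items():
            if g in other_universes[label] and r.relative_rank_of(g) <= low_rank_cut:
                low_elsewhere.append(g)
                break
    low_set = set(low_elsewhere)
    not_low = tuple(g for g in shared if g not in low_set)
    return OverlapSummary(
        top_genes=tuple(top),
        shared_any=len(shared),
        low_ranked_elsewhere=tuple(low_elsewhere),
        not_low_elsewhere=not_low,
        k=k,
        low_rank_cut=low_rank_cut,
    )
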