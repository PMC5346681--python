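"""Threshold-sweep classification metrics for a ranking vs a gold standard.

The top ``floor(fraction * N)`` genes of a centrality ranking are treated as
predicted positives; gold-standard genes present in the network are the
positive class and the remaining network genes the negative class.  Sweeping
the threshold fraction yields recall/accuracy/specificity curves that let
different interactome maps be compared on the same gold standard.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

from .centrality import GeneRanking
from .network_io import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricValues",
    "EvaluationCurve",
    "confusion_at_fraction",
    "metrics",
    "evaluation_curve",
    "default_fractions",
    "write_curve",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold_fraction: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positives(self) -> int:
        return self.tp + self.fn


class MetricValues(NamedTuple):
    recall: float | None
    accuracy: float | None
    specificity: float | None


def _top_count(fraction: float, n: int) -> int:
    # floor rule; round at 1e-9 first so binary representation of e.g.
    # 0.29 * 100 = 28.999... does not lose a gene
    return math.floor(round(fraction * n, 9))


def confusion_at_fraction(
    ranking: GeneRanking, positives: GeneSet, fraction: float
) -> ConfusionCounts:
    """Confusion table when the top ``floor(fraction*N)`` genes are called
    positive.

    ``positives`` must already be restricted to the ranking's gene universe
    (use :func:`ppibench.network_io.restrict_to_network`).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    universe = set(ranking.order)
    if not positives.ids <= universe:
        missing = sorted(positives.ids - universe)[:5]
        raise ValueError(
            "positives contain genes outside the ranking "
            f"(e.g. {missing}); restrict the gene set to the network first"
        )
    n = ranking.n_genes
    k = _top_count(fraction, n)
    predicted = ranking.order[:k]
    tp = sum(1 for g in predicted if g in positives.ids)
    fp = k - tp
    fn = len(positives.ids) - tp
    tn = n - k - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, threshold_fraction=fraction)


def metrics(
    c: ConfusionCounts, total_positives: int | None = None
) -> MetricValues:
    """recall = TP/(TP+FN); accuracy = (TP+TN)/N; specificity = TN/(TN+FP).

    A zero denominator yields ``None`` (undefined), never 0.
    ``total_positives`` switches the recall denominator from within-network
    positives to a common external count (e.g. the full gold-standard list),
    making recall comparable across networks of different coverage.
    """
    pos_denom = total_positives if total_positives is not None else c.tp + c.fn
    if total_positives is not None and total_positives < c.tp + c.fn:
        raise ValueError(
            "total_positives smaller than positives present in the network"
        )
    recall = c.tp / pos_denom if pos_denom > 0 else None
    accuracy = (c.tp + c.tn) / c.n if c.n > 0 else None
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    if recall is None or accuracy is None or specificity is None:
        logger.info(
            "metric undefined at fraction %.3g (zero denominator)",
            c.threshold_fraction,
        )
    return MetricValues(recall=recall, accuracy=accuracy, specificity=specificity)


def default_fractions(step: float = 0.01) -> list[float]:
    """The default threshold grid: 1% steps from 0 to 100%."""
    n = round(1.0 / step)
    return [i * step for i in range(n + 1)]


@dataclass(frozen=True)
class EvaluationCurve:
    """Metric values over a threshold sweep, one row per fraction.

    ``frame`` columns: fraction, TP, FP, TN, FN, recall, accuracy,
    specificity.  Undefined metrics are NaN.
    """

    frame: pd.DataFrame
    positives_n: int
    genes_n: int
    metric: str

    def at(self, fraction: float) -> pd.Series:
        idx = (self.frame["fraction"] - fraction).abs().idxmin()
        return self.frame.loc[idx]


def evaluation_curve(
    ranking: GeneRanking,
    positives: GeneSet,
    fractions: Sequence[float] | None = None,
    total_positives: int | None = None,
) -> EvaluationCurve:
    """Evaluate the ranking at each threshold fraction (ascending)."""
    if fractions is None:
        fractions = default_fractions()
    fractions = list(fractions)
    if any(b < a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be sorted ascending")
    rows = []
    for f in fractions:
        c = confusion_at_fraction(ranking, positives, f)
        m = metrics(c, total_positives=total_positives)
        rows.append(
            {
                "fraction": f,
                "TP": c.tp,
                "FP": c.fp,
                "TN": c.tn,
                "FN": c.fn,
                "recall": math.nan if m.recall is None else m.recall,
                "accuracy": math.nan if m.accuracy is None else m.accuracy,
                "specificity": math.nan
                if m.specificity is None
                else m.specificity,
            }
        )
    return EvaluationCurve(
        frame=pd.DataFrame(rows),
        positives_n=len(positives.ids),
        genes_n=ranking.n_genes,
        metric=ranking.metric,
    )


def write_curve(curve: EvaluationCurve, path: str | Path) -> None:
    curve.frame.to_csv(path, sep="\t", index=False)
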