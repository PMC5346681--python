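"""Somatic mutation frequencies from MAF-like tables, and the
top-vs-bottom rank-group comparison.

A gene's mutation frequency in a cancer type is the number of samples
carrying at least one mutation in that gene divided by the total number of
samples for that cancer — multiple records of one gene in one sample count
once.  The frequencies of the top-ranked and bottom-ranked gene groups from
a centrality ranking are compared with a Wilcoxon rank-sum (Mann-Whitney)
test, one-sided by default since the hypothesis is directional (top-ranked
genes mutate more often).

Only a minimal MAF dialect is parsed: a tab-delimited header containing
``Hugo_Symbol`` (or ``Entrez_Gene_Id``), ``Tumor_Sample_Barcode`` and
``Variant_Classification``.  Cancer-type labels come from a per-file
argument or an optional ``Cancer_Type`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "load_maf",
    "mutation_frequency",
    "compare_rank_groups",
    "MutationTable",
    "RankSumResult",
]

RECORD_COLUMNS = ["gene", "sample", "cancer_type", "variant_class"]


def load_maf(
    path: str | Path,
    cancer_type: str | None = None,
    exclude_silent: bool = False,
) -> pd.DataFrame:
    """Read mutation records from a MAF-like file.

    Returns a DataFrame with columns gene, sample, cancer_type,
    variant_class — one row per data row (after any configured filtering).
    ``exclude_silent`` drops records whose Variant_Classification is
    ``Silent``; by default every record counts as a mutation.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    gene_col = None
    for cand in ("Hugo_Symbol", "Entrez_Gene_Id"):
        if cand in df.columns:
            gene_col = cand
            break
    if gene_col is None:
        raise ValueError(
            f"{path}: missing required gene column "
            "(Hugo_Symbol or Entrez_Gene_Id)"
        )
    for required in ("Tumor_Sample_Barcode", "Variant_Classification"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column {required}")
    out = pd.DataFrame(
        {
            "gene": df[gene_col],
            "sample": df["Tumor_Sample_Barcode"],
            "variant_class": df["Variant_Classification"],
        }
    )
    if "Cancer_Type" in df.columns:
        out["cancer_type"] = df["Cancer_Type"]
    else:
        out["cancer_type"] = cancer_type if cancer_type is not None else path.stem
    bad = out["gene"].isna() | (out["gene"] == "") | out["sample"].isna() | (
        out["sample"] == ""
    )
    if bad.any():
        logger.warning("%s: dropped %d record(s) with empty gene/sample", path, int(bad.sum()))
        out = out[~bad]
    if exclude_silent:
        silent = out["variant_class"] == "Silent"
        if silent.any():
            logger.info("%s: dropped %d Silent record(s)", path, int(silent.sum()))
        out = out[~silent]
    return out[RECORD_COLUMNS].reset_index(drop=True)


@dataclass(frozen=True)
class MutationTable:
    """Gene x cancer-type mutation frequencies with per-cancer sample counts.

    ``freq`` rows are genes, columns cancer types, values in [0, 1];
    ``counts`` holds the underlying mutated-sample counts.
    """

    freq: pd.DataFrame
    counts: pd.DataFrame
    samples_per_cancer: Mapping[str, int]

    def frequency(self, gene: str, cancer_type: str) -> float:
        """Frequency, 0.0 for genes absent from the table."""
        if cancer_type not in self.freq.columns:
            raise KeyError(f"unknown cancer type {cancer_type!r}")
        if gene not in self.freq.index:
            return 0.0
        return float(self.freq.loc[gene, cancer_type])

    def write(self, path: str | Path) -> None:
        self.freq.to_csv(path, sep="\t", index_label="gene", na_rep="0")


def mutation_frequency(
    records: pd.DataFrame,
    total_samples: Mapping[str, int] | None = None,
) -> MutationTable:
    """Per-(gene, cancer) frequency: mutated samples / total samples.

    When ``total_samples`` is not given, totals are inferred as the count of
    distinct sample barcodes seen per cancer — an undercount if some samples
    carry no mutation at all, so generators and pipelines should pass the
    true cohort sizes.
    """
    observed = records.groupby("cancer_type")["sample"].nunique().to_dict()
    if total_samples is None:
        totals = observed
    else:
        totals = dict(total_samples)
        for ct, n_obs in observed.items():
            if ct not in totals:
                raise ValueError(f"total_samples missing cancer type {ct!r}")
            if totals[ct] < n_obs:
                raise ValueError(
                    f"total_samples[{ct!r}]={totals[ct]} is smaller than the "
                    f"{n_obs} distinct samples observed"
                )
    dedup = records.drop_duplicates(subset=["gene", "sample", "cancer_type"])
    counts = (
        dedup.groupby(["gene", "cancer_type"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=sorted(totals), fill_value=0)
    freq = counts.div(pd.Series(totals), axis=1)
    return MutationTable(freq=freq, counts=counts, samples_per_cancer=totals)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str
    alternative: str
    note: str = ""


def compare_rank_groups(
    table: MutationTable,
    top: Sequence[str],
    bottom: Sequence[str],
    cancer_type: str,
    alternative: str = "greater",
) -> RankSumResult:
    """Wilcoxon rank-sum test of top-group vs bottom-group frequencies.

    Genes absent from the table contribute frequency 0.  The exact null
    distribution is used when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie
    correction.  ``alternative='greater'`` tests top > bottom.
    """
    if not top or not bottom:
        raise ValueError("both gene lists must be nonempty")
    x = np.array([table.frequency(g, cancer_type) for g in top], dtype=float)
    y = np.array([table.frequency(g, cancer_type) for g in bottom], dtype=float)
    if np.all(x == x[0]) and np.all(y == x[0]):
        logger.info(
            "%s: all frequencies identical; rank-sum test degenerate",
            cancer_type,
        )
        return RankSumResult(
            statistic=float(len(x) * len(y) / 2.0),
            p_value=1.0,
            method="degenerate",
            alternative=alternative,
            note="all frequencies identical",
        )
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        alternative=alternative,
    )
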