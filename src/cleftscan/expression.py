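"""Expression classification from a raw count table.

Genes are called *expressed* when their mean raw read count across replicates
reaches a floor (default 5 reads), and *strongly expressed* when the mean lies
in the upper quartile of the expressed genes' means. No normalisation is
applied: thresholds are on raw 3'-mRNA-seq counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NOT_EXPRESSED = "not_expressed"
EXPRESSED = "expressed"
STRONGLY_EXPRESSED = "strongly_expressed"
NOT_QUANTIFIED = "not_quantified"


@dataclass
class ExpressionClassification:
    """Per-gene expression class plus the thresholds that produced it."""

    classes: pd.Series  # gene_id -> class label
    mean_counts: pd.Series  # gene_id -> mean raw count
    mean_min: float
    upper_quartile_cut: float | None  # None when no gene is expressed

    @property
    def expressed(self) -> pd.Index:
        """Expressed genes (includes the strongly expressed subset)."""
        return self.classes.index[self.classes != NOT_EXPRESSED]

    @property
    def strongly_expressed(self) -> pd.Index:
        return self.classes.index[self.classes == STRONGLY_EXPRESSED]


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Nearest-rank (type-1) percentile: the ceil(q·n)-th smallest value."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("percentile of empty sequence")
    rank = max(1, math.ceil(q * arr.size))
    return float(arr[rank - 1])


def classify_expression(
    counts: pd.DataFrame,
    mean_min: float = 5.0,
    quartile_method: str = "nearest_rank",
) -> ExpressionClassification:
    """Classify genes from a gene × replicate raw count table.

    A gene is expressed iff its arithmetic mean count across replicates is
    ``>= mean_min``; the strong-expression cut is the 75th percentile of the
    expressed genes' means (``nearest_rank`` by default, or ``linear`` for
    interpolated quantiles), applied inclusively.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("count table must have >= 1 gene and >= 1 replicate")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    means = counts.mean(axis=1)
    expressed = means >= mean_min
    if expressed.any():
        expressed_means = means[expressed].to_numpy()
        if quartile_method == "nearest_rank":
            cut = nearest_rank_percentile(expressed_means, 0.75)
        elif quartile_method == "linear":
            cut = float(np.percentile(expressed_means, 75))
        else:
            raise ValueError(f"unknown quartile method {quartile_method!r}")
    else:
        cut = None
    labels = pd.Series(NOT_EXPRESSED, index=counts.index, dtype=object)
    labels[expressed] = EXPRESSED
    if cut is not None:
        labels[expressed & (means >= cut)] = STRONGLY_EXPRESSED
    return ExpressionClassification(
        classes=labels, mean_counts=means, mean_min=mean_min, upper_quartile_cut=cut
    )


def candidate_tf_report(
    cls: ExpressionClassification,
    candidates: Iterable[str],
    tf_universe: Iterable[str],
) -> tuple[pd.DataFrame, dict]:
    """Cross-reference candidate genes with the motif-TF universe.

    Returns one row per candidate (expression class, universe membership) and
    summary counts: how many candidates are quantified, expressed, strongly
    expressed, and expressed while present in the TF universe.
    """
    universe = set(tf_universe)
    rows = []
    for gene in candidates:
        if gene in cls.classes.index:
            label = cls.classes[gene]
            mean = float(cls.mean_counts[gene])
        else:
            label, mean = NOT_QUANTIFIED, float("nan")
        rows.append(
            {
                "gene_id": gene,
                "in_tf_universe": gene in universe,
                "expression_class": label,
                "mean_count": mean,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene_id", "in_tf_universe", "expression_class", "mean_count"]
    )
    is_expr = table["expression_class"].isin([EXPRESSED, STRONGLY_EXPRESSED])
    summary = {
        "n_candidates": len(table),
        "n_quantified": int((table["expression_class"] != NOT_QUANTIFIED).sum()),
        "n_expressed": int(is_expr.sum()),
        "n_strongly_expressed": int(
            (table["expression_class"] == STRONGLY_EXPRESSED).sum()
        ),
        "n_expressed_in_universe": int((is_expr & table["in_tf_universe"]).sum()),
    }
    return table, summary


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count table (gene_id column + one column per replicate)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
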