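"""Per-gene Kruskal-Wallis differential expression between activity classes.

Expression z-scores need not be normal, so group differences are tested
with the rank-based Kruskal-Wallis H (tie-corrected; with two groups it
is the squared standardized Wilcoxon rank-sum statistic). Raw p-values
below 0.05 are counted — deliberately *without* multiple-testing
correction, matching the protocol this package implements; treat the
significant-gene count as descriptive, not inferential. Each record
also carries the direction of the median shift in active chemicals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ImportanceRecord:
    gene_id: str
    h: float
    p_value: float
    direction: str  # up_in_active | down_in_active | none


def kruskal_wallis_gene(values_active, values_inactive, gene_id: str = "") -> ImportanceRecord:
    """Tie-corrected two-group Kruskal-Wallis test for one gene.

    Identical values across both groups give H=0, p=1 by convention.
    """
    a = np.asarray(values_active, dtype=float)
    b = np.asarray(values_inactive, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.unique(np.concatenate([a, b])).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(a, b)
    med_a, med_b = np.median(a), np.median(b)
    if med_a > med_b:
        direction = "up_in_active"
    elif med_a < med_b:
        direction = "down_in_active"
    else:
        direction = "none"
    return ImportanceRecord(gene_id=gene_id, h=float(h), p_value=float(p), direction=direction)


def importance_table(X, y, gene_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Kruskal-Wallis record per gene column of a signature matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if gene_ids is None:
        gene_ids = [f"f{j}" for j in range(X.shape[1])]
    active, inactive = X[y == 1], X[y == 0]
    records = [
        kruskal_wallis_gene(active[:, j], inactive[:, j], gene_id=g)
        for j, g in enumerate(gene_ids)
    ]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "H": [r.h for r in records],
            "p_value": [r.p_value for r in records],
            "direction": [r.direction for r in records],
        }
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {"gene_id": [r.gene_id for r in records],
         "H": [r.h for r in records],
         "p_value": [r.p_value for r in records],
         "direction": [r.direction for r in records]}
    )


def count_significant(records, alpha: float = 0.05) -> int:
    """Number of genes with raw p strictly below alpha."""
    return int((_as_frame(records)["p_value"] < alpha).sum())


def top_k(records, k: int = 10) -> pd.DataFrame:
    """The k lowest-p genes, ties broken by ascending gene id."""
    frame = _as_frame(records)
    ordered = frame.sort_values(["p_value", "gene_id"], kind="stable").reset_index(drop=True)
    return ordered.head(k)


def selection_capture_rate(selected_genes: Iterable, significant_genes: Iterable) -> float:
    """Fraction of the selected genes that are also significant."""
    selected = set(selected_genes)
    if not selected:
        raise ValueError("capture rate undefined for an empty selection")
    return len(selected & set(significant_genes)) / len(selected)
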