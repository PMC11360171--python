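"""Two-cell-line consensus: mean of per-cell-line activity probabilities.

Each cell line's best model yields a probability that a chemical is
active; the consensus probability is their arithmetic mean, and the
consensus call is active iff that mean is >= 0.5. With exactly two
models a majority vote is ill-defined on disagreement, so the mean
probability is the operative rule throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from qgexar.metrics import MetricSet, confusion, metric_set

THRESHOLD = 0.5


def _validated(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(probs), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one cell-line probability")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return p


@dataclass(frozen=True)
class ConsensusPrediction:
    chemical_id: str
    per_cell_line: Mapping[str, float]
    p_consensus: float
    call: str  # active | inactive


def consensus_probability(
    per_cell_line: Mapping[str, float], chemical_id: str = ""
) -> ConsensusPrediction:
    """Mean the available per-cell-line probabilities; >= 0.5 means active."""
    p = _validated(list(per_cell_line.values()))
    mean = float(p.mean())
    return ConsensusPrediction(
        chemical_id=chemical_id,
        per_cell_line=dict(per_cell_line),
        p_consensus=mean,
        call="active" if mean >= THRESHOLD else "inactive",
    )


def consensus_table(probabilities: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Combine per-cell-line probability series (indexed by chemical_id).

    Every chemical must carry a probability from every cell line; the
    result has one ``p_<cell_line>`` column per model plus
    ``p_consensus`` and ``call``.
    """
    if not probabilities:
        raise ValueError("need at least one cell line")
    frame = pd.DataFrame(
        {f"p_{name.lower()}": s for name, s in probabilities.items()}
    )
    if frame.isna().any().any():
        missing = frame[frame.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing cell-line probability for chemicals {missing[:5]}")
    vals = frame.to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    frame["p_consensus"] = vals.mean(axis=1)
    frame["call"] = np.where(frame["p_consensus"] >= THRESHOLD, "active", "inactive")
    frame.index.name = "chemical_id"
    return frame.reset_index()


def evaluate_consensus(table: pd.DataFrame, labels: pd.Series) -> MetricSet:
    """Score the consensus call against 0/1 labels indexed by chemical_id."""
    indexed = table.set_index("chemical_id")
    missing = [c for c in indexed.index if c not in labels.index]
    if missing:
        raise ValueError(f"no label for chemicals {missing[:5]}")
    y = labels.loc[indexed.index].to_numpy(dtype=int)
    p = indexed["p_consensus"].to_numpy(dtype=float)
    return metric_set(confusion(p, y), probabilities=p, labels=y)
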