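"""Data-cleaning rules and training/validation splitting.

Two cleaning rules govern assembly:

* conflicting activity records for the same (chemical, endpoint) resolve
  to *active* — a single positive literature report outweighs negatives;
* duplicate expression profiles for a chemical resolve to the profile
  with the highest transcriptional activity score (TAS), ties broken by
  input order for determinism.

The validation set is a simple random sample of the chemicals present
in *both* cell lines; each cell line's training set is its remaining
chemicals. Chemicals lacking a signature in a cell line are silently
absent from that cell line's dataset.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from qgexar.containers import (
    ActivityTable,
    SignatureMatrix,
    SplitAssignment,
    TIERS,
    VALID_LABELS,
    gene_tier,
)


def resolve_activity_conflicts(raw: ActivityTable | pd.DataFrame) -> ActivityTable:
    """Collapse repeated (chemical, endpoint) records to a single one.

    Any contradiction resolves to active; ``n_sources`` becomes the count
    of raw records behind the resolved one. Idempotent.
    """
    records = raw.records if isinstance(raw, ActivityTable) else raw
    bad = set(records["label"].unique()) - VALID_LABELS
    if bad:
        raise ValueError(f"invalid activity labels: {sorted(bad)}")

    grouped = records.groupby(["chemical_id", "endpoint"], sort=False)
    resolved = grouped.agg(
        label=("label", lambda s: "active" if (s == "active").any() else "inactive"),
        n_sources=("n_sources", "size"),
        had_conflict=("label", lambda s: s.nunique() > 1),
    ).reset_index()
    # n_sources counts raw records; on an already-resolved table this keeps
    # the previous counts rather than collapsing them to 1
    if records.duplicated(["chemical_id", "endpoint"]).sum() == 0:
        indexed = records.set_index(["chemical_id", "endpoint"])
        key = pd.MultiIndex.from_frame(resolved[["chemical_id", "endpoint"]])
        resolved["n_sources"] = indexed.loc[key, "n_sources"].to_numpy()
        if "had_conflict" in indexed.columns:
            resolved["had_conflict"] = indexed.loc[key, "had_conflict"].to_numpy()
    return ActivityTable(resolved)


def dedupe_profiles_by_tas(matrix: SignatureMatrix) -> SignatureMatrix:
    """Keep one profile per chemical: the one with maximal TAS.

    Ties are broken by input order (first profile wins). A duplicated
    chemical with a missing TAS is an error.
    """
    data = matrix.data
    dup_chems = data.loc[data["chemical_id"].duplicated(keep=False), "chemical_id"]
    if data.loc[data["chemical_id"].isin(dup_chems), "tas"].isna().any():
        raise ValueError("duplicated chemical has a missing TAS")
    # idxmax returns the first occurrence of the maximum -> input-order tie-break
    keep = data.groupby("chemical_id", sort=False)["tas"].idxmax()
    return SignatureMatrix(data.loc[sorted(keep)].reset_index(drop=True))


def filter_gene_tier(matrix: SignatureMatrix, keep: Iterable[str]) -> SignatureMatrix:
    """Restrict gene columns to the requested tiers, preserving order."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep must name at least one gene tier")
    unknown = keep - set(TIERS)
    if unknown:
        raise ValueError(f"unknown gene tiers: {sorted(unknown)}")
    cols = [c for c in matrix.gene_columns if gene_tier(c) in keep]
    return matrix.subset_genes(cols)


def make_split(
    matrices: Mapping[str, SignatureMatrix],
    activity: ActivityTable,
    n_validation: int,
    seed: int = 0,
) -> SplitAssignment:
    """Sample the shared validation set and derive per-cell-line training sets.

    The validation set is drawn uniformly at random (unstratified) from
    the chemicals present in every cell line that also carry an activity
    record; training per cell line is that cell line's labelled chemicals
    minus the validation set.
    """
    labelled = set(activity.records["chemical_id"])
    per_line = {
        name: [c for c in m.chemical_ids.unique() if c in labelled]
        for name, m in matrices.items()
    }
    common = set.intersection(*(set(ids) for ids in per_line.values()))
    if n_validation > len(common):
        raise ValueError(
            f"n_validation={n_validation} exceeds the {len(common)} chemicals "
            "common to all cell lines"
        )
    rng = np.random.default_rng(seed)
    validation = sorted(
        rng.choice(sorted(common), size=n_validation, replace=False).tolist()
    )
    val_set = set(validation)
    training = {
        name: [c for c in ids if c not in val_set] for name, ids in per_line.items()
    }
    return SplitAssignment(training=training, validation=validation, seed=seed)
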