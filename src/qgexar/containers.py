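"""Core tabular containers: signature matrices, activity tables, splits.

A :class:`SignatureMatrix` holds the chemical-by-gene z-score signatures
for one cell line in a single wide :class:`pandas.DataFrame`, one row per
profile, with three metadata columns (``chemical_id``, ``cell_line``,
``tas``) followed by one column per gene. Gene columns carry a tier
prefix — ``L:`` for directly measured landmark transcripts, ``B:`` for
best-inferred genes (gene-level recall > 0.95), ``I:`` for the remaining
lower-confidence inferred genes — so a file on disk is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ["chemical_id", "cell_line", "tas"]

TIERS = ("landmark", "best_inferred", "inferred")
TIER_PREFIX = {"landmark": "L", "best_inferred": "B", "inferred": "I"}
PREFIX_TIER = {v: k for k, v in TIER_PREFIX.items()}

VALID_LABELS = {"active", "inactive"}


def gene_tier(column: str) -> str:
    """Tier of a prefixed gene column name (e.g. ``'L:G0001'`` -> landmark)."""
    prefix = column.split(":", 1)[0]
    try:
        return PREFIX_TIER[prefix]
    except KeyError:
        raise ValueError(f"gene column {column!r} has no recognised tier prefix") from None


@dataclass
class SignatureMatrix:
    """Chemical x gene z-score signatures for a single cell line."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"signature table missing columns {missing}")
        for col in self.gene_columns:
            gene_tier(col)  # raises on unknown prefix
        if len(self.data["cell_line"].unique()) > 1:
            raise ValueError("a SignatureMatrix holds exactly one cell line")
        self.data = self.data.reset_index(drop=True)

    @property
    def gene_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def gene_tiers(self) -> dict[str, str]:
        return {c: gene_tier(c) for c in self.gene_columns}

    @property
    def chemical_ids(self) -> pd.Series:
        return self.data["chemical_id"]

    @property
    def cell_line(self) -> str:
        return str(self.data["cell_line"].iloc[0])

    @property
    def tas(self) -> pd.Series:
        return self.data["tas"]

    @property
    def n_profiles(self) -> int:
        return len(self.data)

    def values(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Z-score matrix as floats, optionally restricted to given gene columns."""
        cols = list(columns) if columns is not None else self.gene_columns
        return self.data[cols].to_numpy(dtype=float)

    def validate(self) -> "SignatureMatrix":
        vals = self.values()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("z-scores must be finite")
        return self

    def subset_chemicals(self, chemical_ids: Iterable) -> "SignatureMatrix":
        keep = set(chemical_ids)
        mask = self.data["chemical_id"].isin(keep)
        return SignatureMatrix(self.data.loc[mask].reset_index(drop=True))

    def subset_genes(self, columns: Sequence[str]) -> "SignatureMatrix":
        return SignatureMatrix(self.data[META_COLUMNS + list(columns)].copy())

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ActivityTable:
    """Per-chemical binary endpoint labels with literature source counts.

    ``records`` columns: ``chemical_id``, ``endpoint`` (ER/AR/TR),
    ``label`` (active/inactive), ``n_sources``; an optional ``provenance``
    column tracks synthetic conflict records.
    """

    records: pd.DataFrame

    REQUIRED = ["chemical_id", "endpoint", "label", "n_sources"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"activity table missing columns {missing}")
        bad = set(self.records["label"].unique()) - VALID_LABELS
        if bad:
            raise ValueError(f"invalid activity labels: {sorted(bad)}")
        self.records = self.records.reset_index(drop=True)

    def for_endpoint(self, endpoint: str) -> pd.DataFrame:
        return self.records[self.records["endpoint"] == endpoint].reset_index(drop=True)

    def binary_labels(self, endpoint: str) -> pd.Series:
        """0/1 label per chemical_id for one endpoint (1 = active)."""
        sub = self.for_endpoint(endpoint)
        dup = sub["chemical_id"].duplicated()
        if dup.any():
            raise ValueError("activity table not resolved: duplicate (chemical, endpoint) pairs")
        return pd.Series(
            (sub["label"] == "active").astype(int).to_numpy(),
            index=sub["chemical_id"].to_numpy(),
            name="label",
        )

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ActivityTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SplitAssignment:
    """Training chemicals per cell line plus the shared validation set."""

    training: Mapping[str, list]
    validation: list
    seed: int = 0

    def __post_init__(self) -> None:
        val = set(self.validation)
        for cell_line, ids in self.training.items():
            overlap = val & set(ids)
            if overlap:
                raise ValueError(
                    f"validation chemicals leak into {cell_line} training: {sorted(overlap)[:5]}"
                )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for cell_line, ids in self.training.items():
            rows.extend({"chemical_id": c, "cell_line": cell_line, "role": "train"} for c in ids)
        rows.extend(
            {"chemical_id": c, "cell_line": "shared", "role": "validation"} for c in self.validation
        )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
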