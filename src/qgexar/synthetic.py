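"""Seeded generator of LINCS-like two-cell-line signature cohorts.

The generator produces chemical-by-gene z-score matrices for two cell
lines (MCF7-like and A549-like by default) with a known ground truth, so
that every downstream stage — deduplication, feature selection, nested
cross-validation, consensus, applicability domain, differential
expression — can be exercised and its parameter recovery measured
without any external download.

Statistical model
-----------------
* Background z-scores are standard normal, drawn independently per
  (chemical, gene, cell line): LINCS signatures are z-scores, so the
  inactive background is N(0, 1) by construction.
* A fraction ``prevalence`` of chemicals is active; for active chemicals
  the ``n_informative`` informative genes are shifted by ``effect_shift``
  z-score units.
* Cell-line divergence is an additive offset per (gene, cell line) drawn
  N(0, ``cell_line_offset_sd``) and applied to every profile of that cell
  line, which separates the cell lines in expression space without
  modeling any biology.
* Genes in the low-confidence "inferred" tier get doubled noise SD, so
  models restricted to landmark genes outperform all-gene models.
* TAS (transcriptional activity score) is Uniform(0, 1), independent of
  the label: it is only ever used as a deduplication key.

Informative genes are sampled from the landmark tier first, overflowing
into the best-inferred tier only when ``n_informative > n_landmark``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from qgexar.containers import ActivityTable, SignatureMatrix, TIER_PREFIX
from qgexar.util import derive_seed

DEFAULT_CELL_LINES = ("MCF7", "A549")

#: Table-1-like prevalence of the ER binding endpoint in MCF7 (484 active
#: of 1552 chemicals).
ER_MCF7_PREVALENCE = 484 / 1552


@dataclass
class SynthConfig:
    """Parameters of a synthetic two-cell-line cohort.

    Defaults emulate the study conditions at a reduced chemical count:
    the full L1000 gene tiers (978 landmark / 9196 best-inferred / 2154
    inferred), 10 informative genes shifted by 2.0 z-score units in
    active chemicals, and the ER/MCF7 class prevalence of 484/1552.
    """

    n_chemicals: int = 300
    n_landmark: int = 978
    n_best_inferred: int = 9196
    n_inferred: int = 2154
    n_informative: int = 10
    effect_shift: float = 2.0
    prevalence: float = ER_MCF7_PREVALENCE
    cell_line_offset_sd: float = 0.5
    inferred_noise_factor: float = 2.0
    duplicate_profile_rate: float = 0.05
    conflict_label_rate: float = 0.05
    endpoint: str = "ER"
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    seed: int = 0

    def validate(self) -> "SynthConfig":
        counts = {
            "n_chemicals": self.n_chemicals,
            "n_landmark": self.n_landmark,
            "n_best_inferred": self.n_best_inferred,
            "n_inferred": self.n_inferred,
            "n_informative": self.n_informative,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0 < self.prevalence < 1:
            raise ValueError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if self.n_informative > self.n_landmark + self.n_best_inferred:
            raise ValueError("n_informative exceeds the landmark + best-inferred catalog")
        for name in ("duplicate_profile_rate", "conflict_label_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.cell_line_offset_sd < 0 or self.effect_shift < 0:
            raise ValueError("effect_shift and cell_line_offset_sd must be >= 0")
        return self

    @property
    def n_genes(self) -> int:
        return self.n_landmark + self.n_best_inferred + self.n_inferred


@dataclass
class GroundTruth:
    """What the generator planted: informative genes, labels, offsets."""

    informative_gene_ids: set
    true_labels: Mapping[str, int]
    cell_line_offsets: Mapping[str, pd.Series] = field(default_factory=dict)


def _gene_catalog(config: SynthConfig) -> list[str]:
    """Tier-prefixed gene ids, landmark first, then best inferred, then inferred."""
    names = []
    counter = 0
    for tier, count in (
        ("landmark", config.n_landmark),
        ("best_inferred", config.n_best_inferred),
        ("inferred", config.n_inferred),
    ):
        prefix = TIER_PREFIX[tier]
        for _ in range(count):
            counter += 1
            names.append(f"{prefix}:G{counter:05d}")
    return names


def generate_cohort(
    config: SynthConfig,
) -> tuple[dict[str, SignatureMatrix], ActivityTable, GroundTruth]:
    """Generate one signature matrix per cell line plus labels and truth.

    All randomness flows from ``config.seed`` through stage-labelled
    derived seeds, so the same config is bit-reproducible.
    """
    config.validate()
    genes = _gene_catalog(config)
    n, p = config.n_chemicals, len(genes)
    chem_ids = [f"CHEM{i:05d}" for i in range(1, n + 1)]

    rng_labels = np.random.default_rng(derive_seed(config.seed, "labels"))
    labels = rng_labels.binomial(1, config.prevalence, size=n)

    # informative genes: landmark tier first, overflow into best inferred
    rng_genes = np.random.default_rng(derive_seed(config.seed, "informative"))
    n_from_landmark = min(config.n_informative, config.n_landmark)
    informative_idx = list(
        rng_genes.choice(config.n_landmark, size=n_from_landmark, replace=False)
    )
    overflow = config.n_informative - n_from_landmark
    if overflow:
        informative_idx += list(
            config.n_landmark
            + rng_genes.choice(config.n_best_inferred, size=overflow, replace=False)
        )
    informative_idx = np.array(sorted(informative_idx), dtype=int)

    inferred_mask = np.array([g.startswith("I:") for g in genes])

    matrices: dict[str, SignatureMatrix] = {}
    offsets: dict[str, pd.Series] = {}
    for cell_line in config.cell_lines:
        rng = np.random.default_rng(derive_seed(config.seed, f"signatures:{cell_line}"))
        offset = rng.normal(0.0, config.cell_line_offset_sd, size=p)
        X = rng.standard_normal((n, p))
        if inferred_mask.any():
            X[:, inferred_mask] *= config.inferred_noise_factor
        X += offset[None, :]
        if informative_idx.size:
            X[np.ix_(labels == 1, informative_idx)] += config.effect_shift
        tas = rng.uniform(0.0, 1.0, size=n)

        frame = pd.DataFrame(X, columns=genes)
        frame.insert(0, "tas", tas)
        frame.insert(0, "cell_line", cell_line)
        frame.insert(0, "chemical_id", chem_ids)
        matrices[cell_line] = SignatureMatrix(frame)
        offsets[cell_line] = pd.Series(offset, index=genes)

    records = pd.DataFrame(
        {
            "chemical_id": chem_ids,
            "endpoint": config.endpoint,
            "label": np.where(labels == 1, "active", "inactive"),
            "n_sources": 1,
            "provenance": "primary",
        }
    )
    truth = GroundTruth(
        informative_gene_ids={genes[i] for i in informative_idx},
        true_labels=dict(zip(chem_ids, labels.tolist())),
        cell_line_offsets=offsets,
    )
    return matrices, ActivityTable(records), truth


def inject_duplicates(
    matrix: SignatureMatrix,
    activity: ActivityTable,
    config: SynthConfig,
) -> tuple[SignatureMatrix, ActivityTable]:
    """Plant duplicate profiles and conflicting activity records.

    A ``duplicate_profile_rate`` fraction of chemicals gains a second,
    noise-perturbed profile with a distinct TAS; a ``conflict_label_rate``
    fraction gains a second activity record with the opposite label,
    flagged ``provenance='conflict_duplicate'``. These are exactly the
    situations the assembly stage's deduplication and conflict-resolution
    rules must handle.
    """
    config.validate()
    data = matrix.data
    n = len(data)
    genes = matrix.gene_columns
    rng = np.random.default_rng(
        derive_seed(config.seed, f"duplicates:{matrix.cell_line}")
    )

    n_dup = int(round(config.duplicate_profile_rate * n))
    if n_dup:
        picked = rng.choice(n, size=n_dup, replace=False)
        dup_rows = data.iloc[picked].copy()
        dup_rows[genes] = dup_rows[genes].to_numpy() + rng.normal(
            0.0, 0.5, size=(n_dup, len(genes))
        )
        new_tas = rng.uniform(0.0, 1.0, size=n_dup)
        ties = new_tas == dup_rows["tas"].to_numpy()
        new_tas[ties] = (new_tas[ties] + 0.5) % 1.0  # measure-zero, but be safe
        dup_rows["tas"] = new_tas
        data = pd.concat([data, dup_rows], ignore_index=True)

    records = activity.records
    rng_act = np.random.default_rng(derive_seed(config.seed, "conflicts"))
    n_conflict = int(round(config.conflict_label_rate * len(records)))
    if n_conflict:
        picked = rng_act.choice(len(records), size=n_conflict, replace=False)
        conflict = records.iloc[picked].copy()
        conflict["label"] = np.where(conflict["label"] == "active", "inactive", "active")
        conflict["provenance"] = "conflict_duplicate"
        records = pd.concat([records, conflict], ignore_index=True)

    return SignatureMatrix(data), ActivityTable(records)
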