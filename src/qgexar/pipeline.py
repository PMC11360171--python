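"""End-to-end orchestration: one config in, a directory of artifacts out.

The run proceeds per endpoint through the full protocol: profile
deduplication and label-conflict resolution, gene-tier filtering, the
shared-validation split, per-cell-line feature selection + nested CV
over the model zoo, best-model refit and validation scoring, the
two-cell-line consensus, the cosine-similarity applicability domain
with its coverage curve, and Kruskal-Wallis importance tables.

Reproducibility: one global seed fans out to per-stage seeds via stable
hashing of stage names, so any stage reruns identically in isolation.
Every TSV artifact starts with a ``# config_hash=...`` comment naming
the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from qgexar._version import __version__ as _pkg_version
from qgexar.assembly import (
    dedupe_profiles_by_tas,
    filter_gene_tier,
    make_split,
    resolve_activity_conflicts,
)
from qgexar.consensus import consensus_table, evaluate_consensus
from qgexar.containers import ActivityTable, SignatureMatrix, TIERS
from qgexar.domain import CosineKNNApplicabilityDomain, coverage_curve
from qgexar.importance import count_significant, importance_table
from qgexar.metrics import confusion, metric_set
from qgexar.models import (
    ALGORITHMS,
    ModelSpec,
    fit_final_and_predict,
    outer_repeated_cv,
    select_best_model,
)
from qgexar.multisurf import multisurf_weights, select_features
from qgexar.synthetic import SynthConfig, generate_cohort, inject_duplicates
from qgexar.util import derive_seed

log = logging.getLogger("qgexar")


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    endpoint: str = "ER"
    signatures: dict[str, str] = field(default_factory=dict)  # cell_line -> TSV path
    activity: str | None = None  # TSV path
    synthetic: dict | None = None  # SynthConfig fields; used when no paths given
    tiers: list[str] = field(default_factory=lambda: ["landmark"])
    selector: bool = True
    models: list[dict] = field(default_factory=lambda: [{"algorithm": a} for a in ALGORITHMS])
    repeats: int = 10
    folds: int = 5
    inner_folds: int = 5
    n_validation: int = 60
    consensus: bool = True
    ad_k: int = 3
    ad_z: float = 0.5
    ad_tiers: list[str] = field(default_factory=lambda: ["landmark", "best_inferred"])
    importance_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "qgexar_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(config: RunConfig) -> list[str]:
    """Exhaustive list of violations (empty list = ok); never fails fast."""
    v: list[str] = []
    if config.folds < 2:
        v.append(f"folds must be >= 2, got {config.folds}")
    if config.inner_folds < 2:
        v.append(f"inner_folds must be >= 2, got {config.inner_folds}")
    if config.repeats < 1:
        v.append(f"repeats must be >= 1, got {config.repeats}")
    if config.n_validation < 0:
        v.append(f"n_validation must be >= 0, got {config.n_validation}")
    if config.ad_k < 1:
        v.append(f"ad_k must be >= 1, got {config.ad_k}")
    if not isinstance(config.seed, int):
        v.append("seed must be an integer")
    for tier_list, name in ((config.tiers, "tiers"), (config.ad_tiers, "ad_tiers")):
        bad = set(tier_list) - set(TIERS)
        if bad:
            v.append(f"{name} contains unknown tiers {sorted(bad)}")
        if not tier_list:
            v.append(f"{name} must name at least one tier")
    if not config.models:
        v.append("models list is empty")
    for m in config.models:
        if "algorithm" not in m:
            v.append(f"model entry missing 'algorithm': {m}")
    if config.signatures or config.activity:
        for cell_line, path in config.signatures.items():
            if not Path(path).exists():
                v.append(f"signature file for {cell_line} not found: {path}")
        if config.activity and not Path(config.activity).exists():
            v.append(f"activity file not found: {config.activity}")
        if not config.activity:
            v.append("signature paths given but no activity path")
        if len(config.signatures) < 2:
            v.append("need signatures for at least two cell lines")
    elif config.synthetic is None:
        v.append("no input data: give signature/activity paths or a synthetic block")
    return v


def _write_tsv(frame: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _load_inputs(config: RunConfig):
    if config.signatures:
        matrices = {
            cl: SignatureMatrix.read_tsv(path) for cl, path in config.signatures.items()
        }
        activity = ActivityTable.read_tsv(config.activity)
    else:
        synth = SynthConfig(**{**(config.synthetic or {}), "seed": derive_seed(config.seed, "synthetic")})
        matrices, activity, _truth = generate_cohort(synth)
        for cl in list(matrices):
            matrices[cl], activity = inject_duplicates(matrices[cl], activity, synth)
    return matrices, activity


def run_all(config: RunConfig) -> Path:
    """Execute the full protocol; returns the artifact directory."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n  " + "\n  ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": chash,
        "qgexar_version": _pkg_version,
        "stage_seeds": {},
        "artifacts": [],
        "stages": {},
    }

    def emit(name: str, frame: pd.DataFrame) -> None:
        _write_tsv(frame, out / name, chash)
        manifest["artifacts"].append(name)

    log.info("loading inputs")
    matrices, raw_activity = _load_inputs(config)

    # --- assembly -----------------------------------------------------
    activity = resolve_activity_conflicts(raw_activity)
    matrices = {cl: dedupe_profiles_by_tas(m) for cl, m in matrices.items()}
    emit("activity_resolved.tsv", activity.records)

    split_seed = derive_seed(config.seed, "split")
    manifest["stage_seeds"]["split"] = split_seed
    split = make_split(matrices, activity, config.n_validation, seed=split_seed)
    split_rows = [
        {"chemical_id": c, "cell_line": cl, "role": "train"}
        for cl, ids in split.training.items()
        for c in ids
    ] + [{"chemical_id": c, "cell_line": "shared", "role": "validation"} for c in split.validation]
    emit("split.tsv", pd.DataFrame(split_rows))

    labels = activity.binary_labels(config.endpoint)
    y_val = labels.loc[split.validation]

    model_specs = [
        ModelSpec(algorithm=m["algorithm"], grid=dict(m.get("grid", {})))
        for m in config.models
    ]

    val_probs: dict[str, pd.Series] = {}
    for cell_line, matrix in matrices.items():
        log.info("cell line %s: assembling training data", cell_line)
        filtered = filter_gene_tier(matrix, config.tiers)
        train_m = filtered.subset_chemicals(split.training[cell_line])
        val_m = filtered.subset_chemicals(split.validation)
        # preserve validation order for consensus alignment
        val_m = SignatureMatrix(
            val_m.data.set_index("chemical_id").loc[split.validation].reset_index()
        )
        X_tr, y_tr = train_m.values(), labels.loc[train_m.chemical_ids].to_numpy()
        X_va = val_m.values()

        if config.selector:
            weights = multisurf_weights(X_tr, y_tr, gene_ids=train_m.gene_columns)
            emit(f"{cell_line}_feature_weights.tsv", weights.to_frame())
            selected = select_features(weights)
            manifest["stages"][f"{cell_line}:selected_genes"] = len(selected)

        reports = []
        for spec in model_specs:
            cv_seed = derive_seed(config.seed, f"cv:{cell_line}:{spec.algorithm}")
            manifest["stage_seeds"][f"cv:{cell_line}:{spec.algorithm}"] = cv_seed
            log.info("cell line %s: outer CV for %s", cell_line, spec.algorithm)
            report = outer_repeated_cv(
                X_tr, y_tr, spec,
                repeats=config.repeats, k=config.folds,
                feature_selector=config.selector,
                inner_k=config.inner_folds, seed=cv_seed,
            )
            emit(f"{cell_line}_cv_{spec.algorithm}.tsv", report.to_frame())
            reports.append((spec, report))

        summary = pd.DataFrame(
            [
                {"algorithm": spec.algorithm, **{
                    f"{m}_{s}": rep.aggregate().loc[m, s]
                    for m in ("se", "sp", "ba", "mcc", "auc") for s in ("mean", "sd")
                }}
                for spec, rep in reports
            ]
        )
        emit(f"{cell_line}_cv_summary.tsv", summary)

        best_spec = select_best_model(reports)
        manifest["stages"][f"{cell_line}:best_algorithm"] = best_spec.algorithm
        final_seed = derive_seed(config.seed, f"final:{cell_line}")
        manifest["stage_seeds"][f"final:{cell_line}"] = final_seed
        clf, probs = fit_final_and_predict(
            X_tr, y_tr, X_va, best_spec,
            feature_selector=config.selector,
            inner_k=config.inner_folds, seed=final_seed,
        )
        val_probs[cell_line] = pd.Series(probs, index=split.validation)
        emit(
            f"{cell_line}_validation_predictions.tsv",
            pd.DataFrame(
                {"chemical_id": split.validation, "p_active": probs,
                 "label": y_val.to_numpy()}
            ),
        )
        if len(split.validation):
            ms = metric_set(
                confusion(probs, y_val.to_numpy()),
                probabilities=probs, labels=y_val.to_numpy(),
            )
            emit(
                f"{cell_line}_validation_metrics.tsv",
                pd.DataFrame([{"algorithm": best_spec.algorithm, **ms.as_dict()}]),
            )

        # --- importance (training data only) -------------------------
        imp = importance_table(X_tr, y_tr, gene_ids=train_m.gene_columns)
        emit(f"{cell_line}_importance.tsv", imp)
        manifest["stages"][f"{cell_line}:significant_genes"] = count_significant(
            imp, alpha=config.importance_alpha
        )

        # --- applicability domain ------------------------------------
        ad_filtered = filter_gene_tier(matrix, config.ad_tiers)
        ad_train = ad_filtered.subset_chemicals(split.training[cell_line])
        ad_val = ad_filtered.subset_chemicals(split.validation)
        ad_val = SignatureMatrix(
            ad_val.data.set_index("chemical_id").loc[split.validation].reset_index()
        )
        ad = CosineKNNApplicabilityDomain(k=config.ad_k, z=config.ad_z).fit(ad_train.values())
        assessment = ad.assess(ad_val.values(), chemical_ids=split.validation)
        emit(f"{cell_line}_ad.tsv", assessment)
        if len(split.validation):
            curve = coverage_curve(
                assessment["mean_top3_cosine"].to_numpy(),
                probs, y_val.to_numpy(), thresholds=np.round(np.arange(0.0, 1.0001, 0.05), 2),
            )
            emit(f"{cell_line}_ad_curve.tsv", curve)

    # --- consensus ----------------------------------------------------
    if config.consensus and len(split.validation):
        table = consensus_table(val_probs)
        emit("consensus.tsv", table)
        ms = evaluate_consensus(table, labels)
        emit("consensus_metrics.tsv", pd.DataFrame([ms.as_dict()]))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run complete: %s", out)
    return out
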