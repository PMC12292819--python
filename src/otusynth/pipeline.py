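"""End-to-end orchestration of the augmentation + discrimination analysis.

Stage order: fixture (or user tables) -> copula augmentation -> quality
gate (adversarial + KS battery) -> LRP extraction -> beta diversity ->
classification with Shapley attribution. Every stage is seeded, writes its
artifacts under the run directory, and is summarized in a JSON manifest
whose structural counts (per-class totals, extraction subset sizes,
per-specimen training counts) make the bookkeeping auditable.

Note on the augmentation layout: the per-specimen per-condition totals
(59 stool / 63 biopsy / 68 saliva) are post-augmentation totals — they sum
to the 190-per-class target, and removing the 6-per-specimen extraction
subset leaves the 53/57/62 per-specimen training counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import betadiv, classify, copula, fixtures, lrp, qc
from .io import (
    CONDITIONS,
    SPECIMENS,
    OtuTable,
    SampleMeta,
    partition,
    read_otu_table,
    write_otu_table,
    write_sample_meta,
)
from .nn import DenseNetSpec

logger = logging.getLogger("otusynth")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "otusynth_run"
    # input: either paths to real tables or a fixture config
    counts_path: str | None = None
    meta_path: str | None = None
    fixture: dict[str, Any] = field(default_factory=dict)
    # augmentation
    targets: dict[str, int] = field(default_factory=lambda: dict(copula.DEFAULT_TARGETS))
    crc_training_subset_size: int = 20
    # qc gate
    alpha: float = 0.05
    ceiling: float = 0.75
    qc_screen_k: int = 500
    qc_cv: int = 5
    # extraction
    extraction_fraction: float = 0.10
    activation: str = "leaky_relu"
    epochs: int = 45
    batch_size: int = 32
    folds: int = 10
    k: int = 64
    lrp_epsilon: float | None = None
    run_activation_sweep: bool = False
    reference_taxa_path: str | None = None
    # classification
    holdout_fraction: float = 0.2
    shap_method: str = "tree_exact"
    force: bool = False

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


@dataclass
class RunManifest:
    config: dict[str, Any]
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    counts: dict[str, Any] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self) -> str:
        def jsonable(obj):
            if isinstance(obj, dict):
                return {
                    ("/".join(map(str, k)) if isinstance(k, tuple) else str(k)): jsonable(v)
                    for k, v in obj.items()
                }
            if isinstance(obj, (list, tuple)):
                return [jsonable(v) for v in obj]
            return obj

        return json.dumps(
            jsonable(
                {
                    "config": self.config,
                    "stages": self.stages,
                    "counts": self.counts,
                    "hashes": self.hashes,
                    "failed_stage": self.failed_stage,
                }
            ),
            indent=2,
            default=str,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    manifest.hashes[str(path)] = _sha256(path)


class QcGateError(RuntimeError):
    """Raised when the synthetic-data quality gate fails and force is off."""


def _load_or_generate(
    config: PipelineConfig, outdir: Path, manifest: RunManifest
) -> tuple[OtuTable, list[SampleMeta]]:
    if config.counts_path:
        table, meta = read_otu_table(
            config.counts_path, orientation="samples", meta_path=config.meta_path
        )
        if meta is None:
            raise ValueError("metadata file required for pipeline input")
        manifest.stages["input"] = {"source": config.counts_path, "n_samples": table.n_samples}
        return table, meta
    fx = dict(config.fixture)
    fx.setdefault("seed", config.seed)
    fc = fixtures.FixtureConfig(**fx)
    table, meta, truth = fixtures.make_fixture(fc)
    write_otu_table(table, outdir / "tables" / "real_counts.tsv", meta,
                    outdir / "tables" / "real_meta.tsv")
    manifest.hashes[str(outdir / "tables" / "real_counts.tsv")] = _sha256(
        outdir / "tables" / "real_counts.tsv"
    )
    pd.DataFrame(
        {"feature_id": truth.planted_feature_ids,
         "enriched_in": [truth.direction[f] for f in truth.planted_feature_ids]}
    ).to_csv(outdir / "tables" / "planted_truth.tsv", sep="\t", index=False)
    manifest.stages["fixture"] = {
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "n_planted": fc.n_planted,
        "effect_size": fc.effect_size,
    }
    return table, meta


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seed = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("augment", "qc", "extract", "classify"), seed_seq.spawn(4)
        )
    }
    try:
        table, meta = _load_or_generate(config, outdir, manifest)

        # --- augmentation -------------------------------------------------
        plan = copula.AugmentationPlan(
            seed=stage_seed["augment"],
            targets=dict(config.targets),
            crc_training_subset_size=config.crc_training_subset_size,
        )
        combined, combined_meta = copula.augment(table, meta, plan)
        write_otu_table(
            combined, outdir / "tables" / "augmented_counts.tsv",
            combined_meta, outdir / "tables" / "augmented_meta.tsv",
        )
        manifest.hashes[str(outdir / "tables" / "augmented_counts.tsv")] = _sha256(
            outdir / "tables" / "augmented_counts.tsv"
        )
        by_cond = partition(combined, combined_meta, by=("condition",))
        per_class_totals = {c[0]: t.n_samples for c, (t, _) in by_cond.items()}
        by_group = partition(combined, combined_meta, by=("condition", "specimen"))
        manifest.counts["per_class_total"] = per_class_totals
        manifest.counts["per_group_total"] = {
            f"{c}/{s}": t.n_samples for (c, s), (t, _) in sorted(by_group.items())
        }
        n_synth = sum(1 for m in combined_meta if m.provenance == "synthetic")
        manifest.stages["augment"] = {
            "plan_targets": plan.targets,
            "n_synthetic": n_synth,
            "seed": stage_seed["augment"],
        }
        logger.info(
            "augmented to per-class totals %s (59/63/68 are per-specimen "
            "post-augmentation totals summing to 190/class)", per_class_totals
        )

        # --- qc gate ------------------------------------------------------
        qc_dir = outdir / "qc"
        qc_dir.mkdir(exist_ok=True)
        gate_pass = True
        qc_summary: dict[str, Any] = {}
        for cond in CONDITIONS:
            real_part = partition(combined, combined_meta, by=("condition", "provenance"))
            key_r, key_s = (cond, "real"), (cond, "synthetic")
            if key_s not in real_part:
                qc_summary[cond] = {"skipped": "no synthetic samples"}
                continue
            r_t, _ = real_part[key_r]
            s_t, _ = real_part[key_s]
            rep = qc.adversarial_report(
                r_t, s_t, k=config.qc_screen_k, seed=stage_seed["qc"],
                ceiling=config.ceiling, cv=config.qc_cv,
            )
            ks = qc.ks_battery(r_t, s_t, alpha=config.alpha, pair_seed=stage_seed["qc"])
            _write(qc.ks_results_frame(ks), qc_dir / f"ks_{cond}.tsv", manifest, index=False)
            n_reject = sum(k_.reject for k_ in ks)
            gate_pass &= rep.passed and n_reject == 0
            qc_summary[cond] = {
                "best_adversarial_accuracy": rep.best_accuracy,
                "adversarial_pass": rep.passed,
                "ks_rejections": n_reject,
                "min_p_adjusted": min(k_.p_adjusted for k_ in ks),
            }
        (qc_dir / "summary.json").write_text(json.dumps(qc_summary, indent=2))
        manifest.stages["qc"] = {**qc_summary, "gate_pass": gate_pass, "seed": stage_seed["qc"]}
        if not gate_pass and not config.force:
            raise QcGateError(f"synthetic-data quality gate failed: {qc_summary}")

        # --- extraction ---------------------------------------------------
        (sub_t, sub_m), (rem_t, rem_m) = lrp.select_extraction_subset(
            combined, combined_meta, fraction=config.extraction_fraction,
            seed=stage_seed["extract"],
        )
        sub_by_cond = partition(sub_t, sub_m, by=("condition",))
        rem_by_cond = partition(rem_t, rem_m, by=("condition",))
        manifest.counts["extraction_subset_per_class"] = {
            c[0]: t.n_samples for c, (t, _) in sub_by_cond.items()
        }
        manifest.counts["remainder_per_class"] = {
            c[0]: t.n_samples for c, (t, _) in rem_by_cond.items()
        }
        rem_groups = partition(rem_t, rem_m, by=("condition", "specimen"))
        manifest.counts["training_per_group"] = {
            f"{c}/{s}": t.n_samples for (c, s), (t, _) in sorted(rem_groups.items())
        }

        spec = DenseNetSpec(
            activation=config.activation, epochs=config.epochs,
            batch_size=config.batch_size, seed=stage_seed["extract"],
        )
        y_sub = np.array([1 if m.condition == "CRC" else 0 for m in sub_m])
        if config.run_activation_sweep:
            sweep, best_act = lrp.activation_sweep(
                sub_t.counts, y_sub, base_spec=spec,
                folds=config.folds, seed=stage_seed["extract"],
            )
            _write(sweep, outdir / "extraction" / "activation_sweep.tsv", manifest, index=False)
            spec = DenseNetSpec(
                activation=best_act, epochs=config.epochs,
                batch_size=config.batch_size, seed=stage_seed["extract"],
            )
        lrp_cfg = lrp.LrpConfig(epsilon=config.lrp_epsilon)
        rmap, top_features = lrp.cross_validated_extraction(
            sub_t.counts, y_sub, sub_t.feature_ids, spec=spec,
            lrp_config=lrp_cfg, folds=config.folds,
            k=min(config.k, sub_t.n_features), seed=stage_seed["extract"],
        )
        _write(rmap.ranked_frame(), outdir / "extraction" / "relevance.tsv", manifest, index=False)
        feature_sets: dict[str, list[str]] = {"full": list(combined.feature_ids),
                                              "extracted": top_features}
        if config.reference_taxa_path:
            ref = Path(config.reference_taxa_path).read_text().splitlines()
            common = lrp.intersect_with_reference(top_features, [r for r in ref if r.strip()])
            feature_sets["common"] = common
            manifest.counts["common_features"] = len(common)
        manifest.stages["extract"] = {
            "k": len(top_features),
            "mean_cv_accuracy": float(np.mean(rmap.fold_accuracies)),
            "activation": spec.activation,
            "seed": stage_seed["extract"],
        }

        # --- beta diversity ----------------------------------------------
        ord_dir = outdir / "ordination"
        meta_by_id = {m.sample_id: m for m in combined_meta}
        for name, feats in feature_sets.items():
            if not feats:
                continue
            view = combined.select_features(feats)
            nonzero = view.counts.sum(axis=1) > 0
            ids = [s for s, keep in zip(view.sample_ids, nonzero) if keep]
            view = view.select_samples(ids)
            transformed = betadiv.sqrt_percent_abundance(view)
            dm = betadiv.bray_curtis_matrix(transformed, view.sample_ids)
            res = betadiv.pcoa(dm)
            coords = res.to_frame(axes=2)
            coords["condition"] = [meta_by_id[s].condition for s in coords.index]
            coords["specimen"] = [meta_by_id[s].specimen for s in coords.index]
            coords["provenance"] = [meta_by_id[s].provenance for s in coords.index]
            _write(coords, ord_dir / f"pcoa_{name}.tsv", manifest)
        manifest.stages["betadiv"] = {"feature_sets": {k: len(v) for k, v in feature_sets.items()}}

        # --- classification + attribution ---------------------------------
        clf_dir = outdir / "classification"
        rem_view = rem_t.select_features(top_features)
        plan_split = classify.stratified_split(
            rem_view, rem_m, holdout_fraction=config.holdout_fraction,
            seed=stage_seed["classify"],
        )
        rem_meta_by_id = {m.sample_id: m for m in rem_m}
        X_tr = rem_view.select_samples(plan_split.train_ids).counts
        X_ho = rem_view.select_samples(plan_split.holdout_ids).counts
        c_tr = [rem_meta_by_id[s].condition for s in plan_split.train_ids]
        c_ho = [rem_meta_by_id[s].condition for s in plan_split.holdout_ids]
        cv_res = classify.compare_models_cv(
            X_tr, c_tr, folds=config.folds, seed=stage_seed["classify"]
        )
        model, report = classify.fit_final_and_evaluate(
            cv_res.best_model, X_tr, c_tr, X_ho, c_ho, seed=stage_seed["classify"]
        )
        _write(
            pd.DataFrame(
                {"fpr": report.roc_fpr, "tpr": report.roc_tpr,
                 "threshold": report.roc_thresholds}
            ),
            clf_dir / "roc.tsv", manifest, index=False,
        )
        _write(
            pd.DataFrame(report.per_class).T, clf_dir / "classification_report.tsv", manifest
        )
        method = config.shap_method
        if method == "tree_exact" and cv_res.best_model != "xgboost":
            method = "permutation_sampled"
        attr = classify.shap_attributions(
            model, X_ho, method=method, feature_ids=top_features,
            sample_ids=plan_split.holdout_ids, seed=stage_seed["classify"],
        )
        plots = classify.export_plot_data(attr, X_ho, c_ho)
        for pname, frame in plots.items():
            _write(frame, clf_dir / f"shap_{pname}.tsv", manifest, index=False)
        # per-specimen attribution sub-reports partition the holdout
        for spec_name in SPECIMENS:
            idx = [
                i for i, s in enumerate(plan_split.holdout_ids)
                if rem_meta_by_id[s].specimen == spec_name
            ]
            if not idx:
                continue
            sub_attr = classify.AttributionReport(
                feature_ids=attr.feature_ids,
                sample_ids=[attr.sample_ids[i] for i in idx],
                base_value=attr.base_value,
                values=attr.values[idx],
                model_output=attr.model_output[idx],
                additivity_residuals=attr.additivity_residuals[idx],
                method=attr.method,
            )
            _write(sub_attr.ranking(), clf_dir / f"shap_summary_{spec_name}.tsv",
                   manifest, index=False)
        manifest.stages["classify"] = {
            "cv_mean_accuracy": cv_res.mean_accuracy,
            "best_model": cv_res.best_model,
            "holdout_accuracy": report.accuracy,
            "holdout_auc": report.auc,
            "n_train": len(plan_split.train_ids),
            "n_holdout": len(plan_split.holdout_ids),
            "shap_method": method,
            "max_additivity_residual": float(np.abs(attr.additivity_residuals).max()),
            "seed": stage_seed["classify"],
        }
    except Exception as exc:
        manifest.failed_stage = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(manifest.to_json())
        raise
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
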