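"""Final classification stage with Shapley attribution.

An 80:20 split balanced over (condition, specimen) strata feeds a 10-fold
cross-validated comparison of three classifiers (polynomial-kernel SVC,
gradient-boosted trees, random forest); the winner is retrained on the
full training subset and evaluated once on the holdout (ROC positive
class: CRC). Per-sample Shapley attributions come either from xgboost's
exact TreeSHAP (``tree_exact``, margin space, additivity to machine
precision) or from an in-package permutation estimator
(``permutation_sampled``) whose telescoping construction is additive by
construction and whose per-feature values converge to the exact Shapley
values of the interventional game.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    auc,
    precision_recall_fscore_support,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .io import OtuTable, SampleMeta
from .qc import SvcParams

__all__ = [
    "SplitPlan",
    "CvResult",
    "HoldoutReport",
    "AttributionReport",
    "MODEL_ORDER",
    "stratified_split",
    "make_model",
    "compare_models_cv",
    "fit_final_and_evaluate",
    "shap_attributions",
    "export_plot_data",
]

MODEL_ORDER = ("svc_poly", "xgboost", "random_forest")
POSITIVE_CLASS = "CRC"


@dataclass
class SplitPlan:
    train_ids: list[str]
    holdout_ids: list[str]
    ratio: float
    seed: int


@dataclass
class CvResult:
    fold_accuracies: dict[str, list[float]]
    mean_accuracy: dict[str, float]
    best_model: str


@dataclass
class HoldoutReport:
    accuracy: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray
    auc: float
    per_class: dict[str, dict[str, float]]  # class -> precision/recall/f1/support


@dataclass
class AttributionReport:
    feature_ids: list[str]
    sample_ids: list[str]
    base_value: float
    values: np.ndarray  # samples x features
    model_output: np.ndarray  # per-sample output the values sum to (with base)
    additivity_residuals: np.ndarray
    method: str

    def ranking(self) -> pd.DataFrame:
        mean_abs = np.abs(self.values).mean(axis=0)
        order = np.lexsort((np.arange(len(mean_abs)), -mean_abs))
        return pd.DataFrame(
            {
                "feature_id": [self.feature_ids[i] for i in order],
                "mean_abs_shap": mean_abs[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def stratified_split(
    table: OtuTable,
    meta: Sequence[SampleMeta],
    holdout_fraction: float = 0.2,
    seed: int = 0,
    min_stratum: int = 5,
) -> SplitPlan:
    """Seeded 80:20 split balanced per (condition, specimen) stratum."""
    rng = np.random.default_rng(seed)
    meta_by_id = {m.sample_id: m for m in meta}
    strata: dict[tuple[str, str], list[str]] = {}
    for s in table.sample_ids:
        m = meta_by_id[s]
        strata.setdefault((m.condition, m.specimen), []).append(s)
    train_ids: list[str] = []
    holdout_ids: list[str] = []
    for key in sorted(strata):
        ids = strata[key]
        if len(ids) < min_stratum:
            raise ValueError(f"stratum {key} has only {len(ids)} samples (< {min_stratum})")
        n_hold = int(round(holdout_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        holdout_ids.extend(ids[i] for i in sorted(perm[:n_hold]))
        train_ids.extend(ids[i] for i in sorted(perm[n_hold:]))
    return SplitPlan(train_ids, holdout_ids, 1 - holdout_fraction, seed)


def make_model(name: str, seed: int = 0, svc_params: SvcParams | None = None):
    """Fresh classifier instance with the pipeline's fixed settings."""
    if name == "svc_poly":
        p = svc_params or SvcParams(C=1.0, gamma=0.01)
        return SVC(kernel="poly", C=p.C, gamma=p.gamma, probability=True, random_state=seed)
    if name == "xgboost":
        return XGBClassifier(
            n_estimators=300,
            max_depth=4,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            base_score=0.5,
        )
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_ORDER}")


def _encode(labels: Sequence[str]) -> np.ndarray:
    return np.asarray([1 if c == POSITIVE_CLASS else 0 for c in labels])


def compare_models_cv(
    X: np.ndarray,
    conditions: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    svc_params: SvcParams | None = None,
) -> CvResult:
    """10-fold CV accuracy per model on shared stratified folds.

    Ties in mean accuracy break toward the listed model order.
    """
    X = np.asarray(X, dtype=float)
    y = _encode(conditions)
    if np.bincount(y).min() < folds:
        raise ValueError(f"need >= {folds} samples per class")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split_list = list(splitter.split(X, y))
    fold_accs: dict[str, list[float]] = {}
    for name in MODEL_ORDER:
        accs = []
        for tr, va in split_list:
            clf = make_model(name, seed=seed, svc_params=svc_params)
            clf.fit(X[tr], y[tr])
            accs.append(float(accuracy_score(y[va], clf.predict(X[va]))))
        fold_accs[name] = accs
    means = {name: float(np.mean(a)) for name, a in fold_accs.items()}
    best = max(MODEL_ORDER, key=lambda n: means[n])  # max is stable under ties
    return CvResult(fold_accs, means, best)


def fit_final_and_evaluate(
    best_model: str,
    X_train: np.ndarray,
    train_conditions: Sequence[str],
    X_holdout: np.ndarray,
    holdout_conditions: Sequence[str],
    seed: int = 0,
    svc_params: SvcParams | None = None,
):
    """Retrain the winning model and evaluate once on the holdout.

    Returns (fitted model, HoldoutReport). ROC scores are the predicted
    probability of the positive (CRC) class.
    """
    if len(X_holdout) == 0:
        raise ValueError("holdout is empty")
    y_tr = _encode(train_conditions)
    y_ho = _encode(holdout_conditions)
    clf = make_model(best_model, seed=seed, svc_params=svc_params)
    clf.fit(np.asarray(X_train, dtype=float), y_tr)
    pred = clf.predict(np.asarray(X_holdout, dtype=float))
    scores = clf.predict_proba(np.asarray(X_holdout, dtype=float))[:, 1]
    fpr, tpr, thr = roc_curve(y_ho, scores)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_ho, pred, labels=[0, 1], zero_division=0
    )
    per_class = {
        name: {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
        }
        for i, name in enumerate(["AP", "CRC"])
    }
    report = HoldoutReport(
        accuracy=float(accuracy_score(y_ho, pred)),
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_thresholds=thr,
        auc=float(auc(fpr, tpr)),
        per_class=per_class,
    )
    return clf, report


# ---------------------------------------------------------------------------
# Shapley attribution


def _margin_function(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, XGBClassifier):
        return lambda Z: model.predict(Z, output_margin=True)
    if hasattr(model, "predict_proba"):
        return lambda Z: model.predict_proba(Z)[:, 1]
    if hasattr(model, "decision_function"):
        return lambda Z: model.decision_function(Z)
    return lambda Z: np.asarray(model.predict(Z), dtype=float)


def _tree_exact(model, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    if not isinstance(model, XGBClassifier):
        raise TypeError(
            "tree_exact attribution is available for xgboost gradient-boosted "
            f"tree models only, got {type(model).__name__}; use permutation_sampled"
        )
    from .treeshap import parse_booster, tree_shap_values

    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    ensemble = parse_booster(model.get_booster(), p)
    # global margin offset (logit of base_score), recovered once against
    # the booster's own prediction; cancels in the additivity residual
    own = ensemble.margin(X[:1])
    ref = model.predict(X[:1], output_margin=True)
    ensemble.base_offset = float(ref[0] - own[0])
    values = tree_shap_values(ensemble, X, p)
    base = ensemble.expected_value
    margins = ensemble.margin(X)
    return base, values, margins


def _permutation_sampled(
    model,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    seed: int,
) -> tuple[float, np.ndarray, np.ndarray]:
    f = _margin_function(model)
    X = np.asarray(X, dtype=float)
    B = np.atleast_2d(np.asarray(background, dtype=float))
    n, p = X.shape
    nb = len(B)
    base = float(f(B).mean())
    rng = np.random.default_rng(seed)
    values = np.zeros((n, p))
    outputs = np.zeros(n)
    chunk = max(1, 8192 // ((p + 1) * nb))  # permutations per model call
    for i in range(n):
        x = X[i]
        # antithetic pairs (each permutation with its reversal) cut the
        # estimator variance; every pair still telescopes exactly
        perms = []
        for _ in range((n_permutations + 1) // 2):
            pm = rng.permutation(p)
            perms.append(pm)
            perms.append(pm[::-1])
        perms = perms[:n_permutations]
        phi = np.zeros(p)
        for c0 in range(0, len(perms), chunk):
            batch = perms[c0 : c0 + chunk]
            m = len(batch)
            Z = np.broadcast_to(B, (m, p + 1, nb, p)).copy()
            for mi, pm in enumerate(batch):
                on: list[int] = []
                for step, j in enumerate(pm, start=1):
                    on.append(j)
                    Z[mi, step][:, on] = x[on]
            vals = f(Z.reshape(-1, p)).reshape(m, p + 1, nb).mean(axis=2)
            for mi, pm in enumerate(batch):
                phi[pm] += np.diff(vals[mi])
        values[i] = phi / len(perms)
        outputs[i] = float(f(x[None, :])[0])
    return base, values, outputs


def shap_attributions(
    model,
    X: np.ndarray,
    background: np.ndarray | None = None,
    method: str = "tree_exact",
    feature_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
    n_permutations: int = 30,
    seed: int = 0,
) -> AttributionReport:
    """Per-sample Shapley attributions for a fitted model.

    ``tree_exact`` (xgboost only) works in margin/log-odds space with exact
    additivity; ``permutation_sampled`` estimates interventional Shapley
    values against a background sample (default: the column means of X).
    """
    X = np.asarray(X, dtype=float)
    if method == "tree_exact":
        base, values, outputs = _tree_exact(model, X)
    elif method == "permutation_sampled":
        if background is None:
            background = X.mean(axis=0, keepdims=True)
        base, values, outputs = _permutation_sampled(
            model, X, background, n_permutations, seed
        )
    else:
        raise ValueError("method must be 'tree_exact' or 'permutation_sampled'")
    residuals = base + values.sum(axis=1) - outputs
    n, p = X.shape
    return AttributionReport(
        feature_ids=list(feature_ids) if feature_ids is not None else [f"f{j}" for j in range(p)],
        sample_ids=list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)],
        base_value=base,
        values=values,
        model_output=outputs,
        additivity_residuals=residuals,
        method=method,
    )


def export_plot_data(
    report: AttributionReport,
    feature_values: np.ndarray,
    sample_conditions: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Summary / beeswarm / force tables from an attribution report.

    The force table orders samples with all AP samples first, then all CRC
    samples (each block in report order), matching the conventional
    force-plot layout.
    """
    Xv = np.asarray(feature_values, dtype=float)
    conds = list(sample_conditions)
    summary = report.ranking()
    bee_rows = []
    for i, sid in enumerate(report.sample_ids):
        for j, fid in enumerate(report.feature_ids):
            bee_rows.append((sid, fid, Xv[i, j], report.values[i, j]))
    beeswarm = pd.DataFrame(
        bee_rows, columns=["sample_id", "feature_id", "feature_value", "shap_value"]
    )
    order = [i for i, c in enumerate(conds) if c == "AP"] + [
        i for i, c in enumerate(conds) if c != "AP"
    ]
    force_rows = []
    for pos, i in enumerate(order):
        for j, fid in enumerate(report.feature_ids):
            force_rows.append(
                (pos, report.sample_ids[i], conds[i], fid, report.values[i, j])
            )
    force = pd.DataFrame(
        force_rows,
        columns=["plot_position", "sample_id", "condition", "feature_id", "shap_value"],
    )
    return {"summary": summary, "beeswarm": beeswarm, "force": force}
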