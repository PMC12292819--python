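"""Quality gating of synthetic OTU data.

Two complementary gates are applied to every synthesis round:

* **adversarial validation** — merge real and synthetic records, label them
  0/1, screen to the top-k chi-squared features, and ask a logistic
  regression and a polynomial-kernel SVC to tell them apart under
  stratified cross-validation. Near-chance accuracy means high fidelity;
  the gate passes when the best classifier stays at or below a
  discriminability ceiling (default 0.75).
* **distributional battery** — per-feature two-sample Kolmogorov–Smirnov
  tests with Bonferroni correction at alpha = 0.05, plus exploratory
  column similarity metrics (mean/STD difference, Spearman, MSE).

Synthetic records that the adversary finds hardest (misclassified as real,
or scored near the 0.5 margin) can be retained preferentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import chi2
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .io import OtuTable

__all__ = [
    "SvcParams",
    "QcReport",
    "KsResult",
    "ColumnStats",
    "RetentionRule",
    "screen_features_chi2",
    "tune_polynomial_svc",
    "adversarial_report",
    "ks_battery",
    "column_similarity",
    "retain_hard_synthetic",
]

C_RANGE = (0.01, 1000.0)
GAMMA_RANGE = (0.0001, 100.0)


@dataclass(frozen=True)
class SvcParams:
    C: float
    gamma: float
    kernel: str = "poly"

    def __post_init__(self) -> None:
        if not (C_RANGE[0] <= self.C <= C_RANGE[1]):
            raise ValueError(f"C={self.C} outside {C_RANGE}")
        if not (GAMMA_RANGE[0] <= self.gamma <= GAMMA_RANGE[1]):
            raise ValueError(f"gamma={self.gamma} outside {GAMMA_RANGE}")


@dataclass
class QcReport:
    per_classifier: dict[str, dict[str, float]]  # name -> metric -> value
    screened_feature_count: int
    ceiling: float
    best_accuracy: float
    passed: bool


@dataclass(frozen=True)
class KsResult:
    feature_id: str
    statistic: float
    p_raw: float
    p_adjusted: float
    reject: bool


@dataclass
class ColumnStats:
    mean_difference: float
    std_difference: float
    spearman_correlation: float
    mse: float


def _as_matrix(x: OtuTable | np.ndarray) -> np.ndarray:
    return x.counts if isinstance(x, OtuTable) else np.asarray(x, dtype=float)


def screen_features_chi2(X: np.ndarray, labels: Sequence, k: int) -> np.ndarray:
    """Indices of the k features with the largest chi-squared statistic.

    Ties (and undefined statistics of all-zero features, scored lowest)
    break toward the smaller feature index; returned indices are sorted
    ascending. Equivalent to sklearn's SelectKBest(chi2, k) with a
    deterministic tie rule.
    """
    X = _as_matrix(X)
    labels = np.asarray(labels)
    if np.any(X < 0):
        raise ValueError("chi-squared screening requires nonnegative features")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two label classes")
    if k < 1:
        raise ValueError("k must be >= 1")
    p = X.shape[1]
    if k >= p:
        return np.arange(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores, _ = chi2(X, labels)
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.lexsort((np.arange(p), -scores))
    return np.sort(order[:k])


def tune_polynomial_svc(
    X: np.ndarray,
    labels: Sequence,
    n_trials: int = 100,
    seed: int = 0,
    cv: int = 5,
) -> tuple[SvcParams, float]:
    """Seeded random search for polynomial-SVC (C, gamma).

    Draws are log-uniform over C in [0.01, 1000] and gamma in [1e-4, 100];
    the objective is mean stratified-CV accuracy over ``cv`` folds; the
    best of ``n_trials`` trials wins (first trial wins ties).
    """
    X = _as_matrix(X)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 samples each")
    rng = np.random.default_rng(seed)
    splitter = StratifiedKFold(n_splits=min(cv, counts.min()), shuffle=True, random_state=seed)
    best: tuple[float, SvcParams] | None = None
    for _ in range(n_trials):
        C = float(np.exp(rng.uniform(np.log(C_RANGE[0]), np.log(C_RANGE[1]))))
        gamma = float(np.exp(rng.uniform(np.log(GAMMA_RANGE[0]), np.log(GAMMA_RANGE[1]))))
        params = SvcParams(C=C, gamma=gamma)
        clf = SVC(kernel="poly", C=C, gamma=gamma)
        score = float(cross_val_score(clf, X, labels, cv=splitter).mean())
        if best is None or score > best[0]:
            best = (score, params)
    assert best is not None
    return best[1], best[0]


def adversarial_report(
    real: OtuTable | np.ndarray,
    synthetic: OtuTable | np.ndarray,
    svc_params: SvcParams | None = None,
    k: int = 500,
    seed: int = 0,
    ceiling: float = 0.75,
    cv: int = 5,
) -> QcReport:
    """Real-vs-synthetic adversarial classification report.

    Classes are balanced by seeded subsampling of the larger side, features
    are screened to the top-k by chi-squared, and both classifiers are
    evaluated with stratified cross-validated predictions.
    """
    Xr, Xs = _as_matrix(real), _as_matrix(synthetic)
    if Xr.size == 0 or Xs.size == 0:
        raise ValueError("empty input")
    if Xr.shape[1] != Xs.shape[1]:
        raise ValueError("real and synthetic tables must share the feature axis")
    rng = np.random.default_rng(seed)
    n = min(len(Xr), len(Xs))
    if len(Xr) > n:
        Xr = Xr[np.sort(rng.choice(len(Xr), n, replace=False))]
    if len(Xs) > n:
        Xs = Xs[np.sort(rng.choice(len(Xs), n, replace=False))]
    X = np.vstack([Xr, Xs])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])

    sel = screen_features_chi2(X, y, min(k, X.shape[1]))
    Xk = X[:, sel]

    if svc_params is None:
        svc_params = SvcParams(C=1.0, gamma=0.01)
    # counts span orders of magnitude; z-scoring inside the fold keeps the
    # logistic solver well-conditioned without touching the chi2 screen
    classifiers = {
        "logistic_regression": make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000)
        ),
        "svc_poly": SVC(kernel="poly", C=svc_params.C, gamma=svc_params.gamma),
    }
    splitter = StratifiedKFold(n_splits=min(cv, n), shuffle=True, random_state=seed)
    per_clf: dict[str, dict[str, float]] = {}
    for name, clf in classifiers.items():
        pred = cross_val_predict(clf, Xk, y, cv=splitter)
        per_clf[name] = {
            "accuracy": float(accuracy_score(y, pred)),
            "precision": float(precision_score(y, pred, zero_division=0)),
            "recall": float(recall_score(y, pred, zero_division=0)),
            "f1": float(f1_score(y, pred, zero_division=0)),
        }
    best_acc = max(m["accuracy"] for m in per_clf.values())
    return QcReport(
        per_classifier=per_clf,
        screened_feature_count=len(sel),
        ceiling=ceiling,
        best_accuracy=best_acc,
        passed=best_acc <= ceiling,
    )


def ks_battery(
    real_table: OtuTable,
    synth_table: OtuTable,
    alpha: float = 0.05,
    pair_seed: int | None = None,
) -> list[KsResult]:
    """Per-feature two-sample KS tests with Bonferroni correction.

    When ``pair_seed`` is given and sample counts differ, the larger table
    is subsampled (seeded) to pair equal counts, mirroring the equal-count
    pairing the battery is designed for. Columns constant and identical in
    both tables report statistic 0, p 1.
    """
    if real_table.feature_ids != synth_table.feature_ids:
        raise ValueError("feature axes differ between real and synthetic tables")
    Xr, Xs = real_table.counts, synth_table.counts
    if pair_seed is not None and len(Xr) != len(Xs):
        rng = np.random.default_rng(pair_seed)
        n = min(len(Xr), len(Xs))
        if len(Xr) > n:
            Xr = Xr[np.sort(rng.choice(len(Xr), n, replace=False))]
        else:
            Xs = Xs[np.sort(rng.choice(len(Xs), n, replace=False))]

    n_tests = len(real_table.feature_ids)
    stats_raw: list[tuple[float, float]] = []
    for j in range(n_tests):
        r, s = Xr[:, j], Xs[:, j]
        if r.min() == r.max() == s.min() == s.max():
            stats_raw.append((0.0, 1.0))
        else:
            # count columns are tie-heavy; the exact method is unreliable
            # under ties, so the asymptotic p is used throughout
            res = stats.ks_2samp(r, s, method="asymp")
            stats_raw.append((float(res.statistic), float(res.pvalue)))
    p_raw = np.array([p for _, p in stats_raw])
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="bonferroni")
    return [
        KsResult(fid, stat, float(pr), float(pa), bool(rej))
        for fid, (stat, pr), pa, rej in zip(
            real_table.feature_ids, stats_raw, p_adj, reject
        )
    ]


def ks_results_frame(results: Sequence[KsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.statistic, r.p_raw, r.p_adjusted, r.reject) for r in results],
        columns=["feature_id", "statistic", "p_raw", "p_adjusted", "reject"],
    )


def column_similarity(
    real_table: OtuTable | np.ndarray, synth_table: OtuTable | np.ndarray
) -> ColumnStats:
    """Exploratory paired-column similarity metrics, averaged over columns.

    Spearman is undefined for constant columns; those columns are skipped
    in the Spearman average (all columns still contribute to the other
    three metrics).
    """
    Xr, Xs = _as_matrix(real_table), _as_matrix(synth_table)
    if Xr.shape != Xs.shape:
        raise ValueError(f"shape mismatch {Xr.shape} vs {Xs.shape} (pair samples first)")
    mean_diff = np.abs(Xr.mean(axis=0) - Xs.mean(axis=0))
    std_diff = np.abs(Xr.std(axis=0, ddof=1) - Xs.std(axis=0, ddof=1))
    mse = ((Xr - Xs) ** 2).mean(axis=0)
    rhos = []
    for j in range(Xr.shape[1]):
        if np.ptp(Xr[:, j]) == 0 or np.ptp(Xs[:, j]) == 0:
            continue
        rho = stats.spearmanr(Xr[:, j], Xs[:, j]).statistic
        if np.isfinite(rho):
            rhos.append(rho)
    return ColumnStats(
        mean_difference=float(mean_diff.mean()),
        std_difference=float(std_diff.mean()),
        spearman_correlation=float(np.mean(rhos)) if rhos else float("nan"),
        mse=float(mse.mean()),
    )


@dataclass(frozen=True)
class RetentionRule:
    """Keep synthetic records misclassified as real and/or near the margin."""

    margin_threshold: float = 0.1
    include_misclassified: bool = True


def retain_hard_synthetic(
    synthetic: OtuTable | np.ndarray,
    classifier_scores: Sequence[float],
    rule: RetentionRule = RetentionRule(),
) -> tuple[np.ndarray, np.ndarray]:
    """Return (retained row indices, boolean mask) of hard synthetic samples.

    ``classifier_scores`` are the adversary's probabilities that each
    synthetic sample is synthetic; scores < 0.5 are misclassifications.
    """
    scores = np.asarray(classifier_scores, dtype=float)
    X = _as_matrix(synthetic)
    if len(scores) != len(X):
        raise ValueError(
            f"{len(scores)} scores for {len(X)} synthetic samples"
        )
    mask = np.abs(scores - 0.5) < rule.margin_threshold
    if rule.include_misclassified:
        mask |= scores < 0.5
    return np.flatnonzero(mask), mask
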