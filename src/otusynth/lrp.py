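"""Relevance-based taxon selection via layer-wise relevance propagation.

The epsilon rule redistributes the network output backwards through each
dense layer:

    R_j = sum_k  a_j w_jk / (z_k + eps * sign(z_k)) * R_k,
    z_k = sum_j a_j w_jk + b_k

with relevance initialized at the pre-sigmoid logit (or the sigmoid
probability, by config). ``eps`` stabilizes near-zero denominators; by
default it is relative — 1e-2 times the mean |z| of the layer — so the
rule is scale-free; ``sign(0)`` is taken as +1. Bias relevance is
absorbed, so conservation (sum of input relevances equals the output) is
exact only in the zero-bias limit.

Feature extraction runs inside stratified cross-validation: per fold the
network is trained on the fold-train split (features z-scored with
fold-train statistics) and relevances are computed for each fold-validation
sample; per-taxon scores are the mean of |relevance| across samples and
folds, and the top-k taxa by score form the extracted feature set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .io import CONDITIONS, SPECIMENS, OtuTable, SampleMeta, partition
from .nn import ACTIVATIONS, DenseNet, DenseNetSpec, train_dense_net

__all__ = [
    "LrpConfig",
    "RelevanceMap",
    "lrp_epsilon",
    "select_extraction_subset",
    "activation_sweep",
    "cross_validated_extraction",
    "intersect_with_reference",
]


@dataclass(frozen=True)
class LrpConfig:
    epsilon: float | None = None  # None => relative: 1e-2 * mean |z| per layer
    output_seed: str = "logit"  # or "probability"
    aggregation: str = "mean_abs"  # or "mean_signed"

    def __post_init__(self) -> None:
        if self.epsilon is not None and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.output_seed not in ("logit", "probability"):
            raise ValueError("output_seed must be 'logit' or 'probability'")
        if self.aggregation not in ("mean_abs", "mean_signed"):
            raise ValueError("aggregation must be 'mean_abs' or 'mean_signed'")


@dataclass
class RelevanceMap:
    feature_ids: list[str]
    scores: np.ndarray  # one aggregated relevance per feature
    fold_accuracies: list[float]

    def ranked_frame(self) -> pd.DataFrame:
        order = np.lexsort((np.arange(len(self.scores)), -self.scores))
        return pd.DataFrame(
            {
                "feature_id": [self.feature_ids[i] for i in order],
                "score": self.scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


def _sign(z: np.ndarray) -> np.ndarray:
    s = np.sign(z)
    s[s == 0] = 1.0
    return s


def lrp_epsilon(net: DenseNet, x: np.ndarray, config: LrpConfig = LrpConfig()) -> np.ndarray:
    """Per-input relevance vector for a single input."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != net.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {x.shape[0]} does not match network "
            f"input {net.weights[0].shape[0]}"
        )
    acts, zs = net.forward_cached(x[None, :])
    logit = float(acts[-1][0, 0])
    if config.output_seed == "logit":
        R = np.array([logit])
    else:
        R = np.array([1.0 / (1.0 + np.exp(-logit))])
    for l in range(net.n_layers - 1, -1, -1):
        a = acts[l][0]  # input activations of layer l
        z = zs[l][0]  # its affine outputs
        if config.epsilon is None:
            eps = 1e-2 * np.mean(np.abs(z))
        else:
            eps = config.epsilon
        denom = z + eps * _sign(z)
        if np.any(denom == 0):
            raise ZeroDivisionError(
                f"layer {l}: zero denominator with epsilon={eps}; "
                "use a positive stabilizer"
            )
        R = a * (net.weights[l] @ (R / denom))
    return R


def select_extraction_subset(
    table: OtuTable,
    meta: Sequence[SampleMeta],
    fraction: float = 0.10,
    seed: int = 0,
) -> tuple[tuple[OtuTable, list[SampleMeta]], tuple[OtuTable, list[SampleMeta]]]:
    """Split off a specimen-balanced extraction subset per condition.

    Per condition the subset size is the largest multiple of 3 not
    exceeding ``fraction`` times the condition's sample count, drawn
    equally (seeded) from the three specimens; the remainder is the
    complement. With the 190-per-class layout and fraction 0.10 this
    yields 18 + 172 per condition.
    """
    rng = np.random.default_rng(seed)
    groups = partition(table, meta, by=("condition", "specimen"))
    cond_totals = {
        cond: sum(
            groups[(cond, s)][0].n_samples for s in SPECIMENS if (cond, s) in groups
        )
        for cond in CONDITIONS
    }
    subset_ids: list[str] = []
    for cond in CONDITIONS:
        quota = 3 * int(np.floor(fraction * cond_totals[cond] / 3))
        per_spec = quota // 3
        if per_spec == 0:
            continue
        for spec in SPECIMENS:
            if (cond, spec) not in groups:
                raise ValueError(f"no samples for group ({cond}, {spec})")
            g_table, _ = groups[(cond, spec)]
            if g_table.n_samples < per_spec:
                raise ValueError(
                    f"group ({cond}, {spec}) has {g_table.n_samples} samples; "
                    f"quota is {per_spec}"
                )
            pick = np.sort(rng.choice(g_table.n_samples, per_spec, replace=False))
            subset_ids.extend(g_table.sample_ids[i] for i in pick)
    subset_set = set(subset_ids)
    remainder_ids = [s for s in table.sample_ids if s not in subset_set]
    meta_by_id = {m.sample_id: m for m in meta}
    sub = (table.select_samples(subset_ids), [meta_by_id[s] for s in subset_ids])
    rem = (table.select_samples(remainder_ids), [meta_by_id[s] for s in remainder_ids])
    return sub, rem


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def activation_sweep(
    X: np.ndarray,
    labels: np.ndarray,
    activations: Sequence[str] = ACTIVATIONS,
    base_spec: DenseNetSpec = DenseNetSpec(),
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, str]:
    """Compare hidden activations under identical stratified CV folds.

    Fold assignment and per-fold training seeds are shared across
    variants, so the comparison is paired. Returns the per-variant mean
    accuracy table and the argmax variant (ties -> first listed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class, got {counts}")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split_list = list(splitter.split(X, y))
    rows = []
    for act in activations:
        accs = []
        for f, (tr, va) in enumerate(split_list):
            Xt, Xv = _standardize(X[tr], X[va])
            spec = DenseNetSpec(
                hidden_widths=base_spec.hidden_widths,
                activation=act,
                leaky_alpha=base_spec.leaky_alpha,
                epochs=base_spec.epochs,
                batch_size=base_spec.batch_size,
                learning_rate=base_spec.learning_rate,
                seed=seed * 1000 + f,
            )
            net = train_dense_net(Xt, y[tr], spec)
            accs.append(float(np.mean(net.predict(Xv) == y[va])))
        rows.append((act, float(np.mean(accs)), accs))
    frame = pd.DataFrame(
        [(a, m) for a, m, _ in rows], columns=["activation", "mean_cv_accuracy"]
    )
    best = max(rows, key=lambda r: r[1])  # max is stable: first of ties wins
    return frame, best[0]


def cross_validated_extraction(
    X: np.ndarray,
    labels: np.ndarray,
    feature_ids: Sequence[str],
    spec: DenseNetSpec = DenseNetSpec(),
    lrp_config: LrpConfig = LrpConfig(),
    folds: int = 10,
    k: int = 64,
    seed: int = 0,
) -> tuple[RelevanceMap, list[str]]:
    """Rank taxa by cross-validated LRP relevance and return the top-k.

    Ties in the final score break toward the smaller feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    p = X.shape[1]
    if k > p:
        raise ValueError(f"k={k} exceeds n_features={p}")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    fold_accs = []
    for f, (tr, va) in enumerate(splitter.split(X, y)):
        Xt, Xv = _standardize(X[tr], X[va])
        fold_spec = DenseNetSpec(
            hidden_widths=spec.hidden_widths,
            activation=spec.activation,
            leaky_alpha=spec.leaky_alpha,
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            seed=seed * 1000 + f,
        )
        net = train_dense_net(Xt, y[tr], fold_spec)
        fold_accs.append(float(np.mean(net.predict(Xv) == y[va])))
        rel = np.array([lrp_epsilon(net, xv, lrp_config) for xv in Xv])
        if lrp_config.aggregation == "mean_abs":
            fold_scores.append(np.abs(rel).mean(axis=0))
        else:
            fold_scores.append(rel.mean(axis=0))
    scores = np.mean(fold_scores, axis=0)
    rmap = RelevanceMap(list(feature_ids), scores, fold_accs)
    order = np.lexsort((np.arange(p), -scores))
    top = [feature_ids[i] for i in order[:k]]
    return rmap, top


def _normalize_ws(s: str) -> str:
    return " ".join(s.split())


def intersect_with_reference(
    features: Sequence[str], reference_taxa: Sequence[str]
) -> list[str]:
    """Order-preserving intersection by whitespace-normalized exact match."""
    ref = {_normalize_ws(r) for r in reference_taxa}
    return [f for f in features if _normalize_ws(f) in ref]
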