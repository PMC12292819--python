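"""Gaussian-copula synthesis of OTU count tables.

The synthesizer couples per-feature Gaussian-KDE marginals through a latent
multivariate-normal correlation structure:

1. fit a 1-D KDE to every feature column (constant columns get a
   degenerate point-mass model);
2. map observations to latent normal scores ``z = Phi^-1(F_j(x))`` with the
   empirical-smooth cdf clipped to ``(delta, 1 - delta)``, ``delta = 1/(4n)``,
   to keep scores finite;
3. estimate the latent correlation from the scores, shrink toward the
   identity (``lambda = min(0.5, p / (10 n))``; the p >> n regime makes the
   raw estimate singular) and project to the nearest positive-semidefinite
   correlation matrix;
4. sample latent Gaussian vectors, push them through ``Phi`` and each
   marginal's inverse cdf, clip to the observed [min, max] when
   ``enforce_min_max`` is set, and round to the nearest integer when
   ``enforce_rounding`` is set.

The augmentation schedule balances the AP and CRC classes: every
(condition, specimen) group is expanded in rounds, each round the size of
the group's real sample count, until the per-group target is reached
(defaults: 59 stool / 63 biopsy / 68 saliva per condition, 190 per class).
CRC groups are fitted on a seeded random subset (default 20 per specimen)
while all AP samples are used, preserving the smaller class's variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from .io import CONDITIONS, SPECIMENS, OtuTable, SampleMeta, partition

__all__ = [
    "MarginalModel",
    "CopulaModel",
    "AugmentationPlan",
    "SyntheticBatch",
    "fit_marginal",
    "fit_copula",
    "sample_synthetic",
    "augment",
]

DEFAULT_TARGETS: dict[str, int] = {"stool": 59, "biopsy": 63, "saliva": 68}


@dataclass
class MarginalModel:
    """One-dimensional marginal: Gaussian KDE or a degenerate constant."""

    kind: str  # "gaussian_kde" | "constant"
    support_min: float
    support_max: float
    bandwidth: float
    training_values: np.ndarray

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "constant":
            return (x >= self.support_min).astype(float)
        # mean of kernel cdfs; strictly increasing on the real line
        u = ndtr((x[..., None] - self.training_values) / self.bandwidth)
        return u.mean(axis=-1)

    def ppf(self, u: np.ndarray | float) -> np.ndarray:
        """Inverse cdf by vectorized bisection (cdf is strictly monotone)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("ppf defined for u in (0, 1)")
        if self.kind == "constant":
            return np.full(u.shape, self.support_min)
        lo = np.full(u.shape, self.support_min - 10 * self.bandwidth)
        hi = np.full(u.shape, self.support_max + 10 * self.bandwidth)
        # widen until the bracket surely contains all quantiles
        while np.any(self.cdf(lo) > u):
            lo -= 10 * self.bandwidth
        while np.any(self.cdf(hi) < u):
            hi += 10 * self.bandwidth
        for _ in range(90):  # bracket width / 2^90: exact to double precision
            mid = 0.5 * (lo + hi)
            below = self.cdf(mid) < u
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)


def fit_marginal(values: Sequence[float] | np.ndarray) -> MarginalModel:
    """Fit a Gaussian-KDE marginal with Scott's rule-of-thumb bandwidth."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError(f"need >= 2 values to fit a marginal, got {values.size}")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return MarginalModel("constant", vmin, vmax, 0.0, values.copy())
    bandwidth = float(stats.gaussian_kde(values).factor * values.std(ddof=1))
    return MarginalModel("gaussian_kde", vmin, vmax, bandwidth, values.copy())


@dataclass
class CopulaModel:
    marginals: list[MarginalModel]
    latent_corr: np.ndarray
    enforce_min_max: bool = True
    enforce_rounding: bool = True
    feature_ids: list[str] | None = None
    raw_corr: np.ndarray | None = None  # pre-shrinkage estimate, kept for diagnostics

    def __post_init__(self) -> None:
        C = np.asarray(self.latent_corr, dtype=float)
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("latent correlation must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("latent correlation must have unit diagonal")
        self.latent_corr = C
        self._factor: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return len(self.marginals)

    def factor(self) -> np.ndarray:
        """Square root of the (PSD) latent correlation via eigendecomposition."""
        if self._factor is None:
            w, V = np.linalg.eigh(self.latent_corr)
            w = np.clip(w, 0.0, None)
            self._factor = V * np.sqrt(w)
        return self._factor


@dataclass
class SyntheticBatch:
    """Synthesized samples plus their generating group and round index."""

    table: OtuTable
    condition: str | None = None
    specimen: str | None = None
    round_index: int = 0


def _nearest_psd_correlation(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    C_psd = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(C_psd), 1e-12, None))
    C_psd = C_psd / np.outer(d, d)
    np.fill_diagonal(C_psd, 1.0)
    return 0.5 * (C_psd + C_psd.T)


def fit_copula(
    table: OtuTable | np.ndarray,
    enforce_min_max: bool = True,
    enforce_rounding: bool = True,
    shrinkage: float | None = None,
) -> CopulaModel:
    """Fit marginals and latent correlation to a table of observations."""
    if isinstance(table, OtuTable):
        X = table.counts
        feature_ids = list(table.feature_ids)
    else:
        X = np.asarray(table, dtype=float)
        feature_ids = None
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need >= 2 samples to fit a copula, got {n}")

    marginals = [fit_marginal(X[:, j]) for j in range(p)]
    delta = 1.0 / (4 * n)
    Z = np.zeros((n, p))
    nondeg = np.zeros(p, dtype=bool)
    for j, m in enumerate(marginals):
        if m.kind == "constant":
            continue
        u = np.clip(m.cdf(X[:, j]), delta, 1 - delta)
        Z[:, j] = ndtri(u)
        nondeg[j] = True

    S = np.eye(p)
    if nondeg.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            sub = np.corrcoef(Z[:, nondeg].T)
        sub = np.atleast_2d(np.nan_to_num(sub, nan=0.0))
        np.fill_diagonal(sub, 1.0)
        ix = np.flatnonzero(nondeg)
        S[np.ix_(ix, ix)] = sub

    lam = min(0.5, p / (10.0 * n)) if shrinkage is None else shrinkage
    C = lam * np.eye(p) + (1 - lam) * S
    C = _nearest_psd_correlation(C)
    return CopulaModel(marginals, C, enforce_min_max, enforce_rounding, feature_ids, raw_corr=S)


def sample_synthetic(
    model: CopulaModel,
    n: int,
    seed: int,
    condition: str | None = None,
    specimen: str | None = None,
    round_index: int = 0,
    sample_prefix: str = "syn",
) -> SyntheticBatch:
    """Draw ``n`` synthetic samples from a fitted copula model (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not model.marginals:
        raise ValueError("model has no fitted marginals")
    rng = np.random.default_rng(seed)
    p = model.n_features
    Z = rng.standard_normal((n, p)) @ model.factor().T
    U = np.clip(ndtr(Z), 1e-12, 1 - 1e-12)
    X = np.empty((n, p))
    for j, m in enumerate(model.marginals):
        X[:, j] = m.ppf(U[:, j])
        if model.enforce_min_max:
            X[:, j] = np.clip(X[:, j], m.support_min, m.support_max)
    if model.enforce_rounding:
        X = np.round(X)
        X[X == -0.0] = 0.0
    feature_ids = model.feature_ids or [f"f{j:05d}" for j in range(p)]
    tag = "_".join(str(t) for t in (condition, specimen) if t is not None)
    prefix = f"{sample_prefix}_{tag}" if tag else sample_prefix
    sample_ids = [f"{prefix}_r{round_index}_{i:03d}" for i in range(n)]
    return SyntheticBatch(
        OtuTable(sample_ids, feature_ids, X), condition, specimen, round_index
    )


@dataclass
class AugmentationPlan:
    """Per-(condition, specimen) augmentation targets.

    ``targets`` maps specimen -> per-condition total after augmentation;
    the defaults (59/63/68) sum to the 190-per-class layout. CRC groups are
    fitted on a seeded random subset of ``crc_training_subset_size`` real
    samples; AP groups use all their real samples.
    """

    seed: int
    targets: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    crc_training_subset_size: int = 20
    enforce_min_max: bool = True
    enforce_rounding: bool = True

    def per_condition_total(self) -> int:
        return sum(self.targets.values())


def augment(
    table: OtuTable,
    meta: Sequence[SampleMeta],
    plan: AugmentationPlan,
) -> tuple[OtuTable, list[SampleMeta]]:
    """Expand every (condition, specimen) group to its planned total.

    Returns the combined dataset (real samples first within each group,
    then synthetic rounds) with provenance recorded in the metadata.
    """
    groups = partition(table, meta, by=("condition", "specimen"))
    seed_seq = np.random.SeedSequence(plan.seed)
    # deterministic group order regardless of input ordering
    ordered_keys = [
        (cond, spec)
        for cond in CONDITIONS
        for spec in SPECIMENS
        if (cond, spec) in groups
    ]
    child_seeds = {key: s for key, s in zip(ordered_keys, seed_seq.spawn(len(ordered_keys)))}

    all_tables: list[OtuTable] = []
    all_meta: list[SampleMeta] = []
    for key in ordered_keys:
        cond, spec = key
        g_table, g_meta = groups[key]
        n_real = g_table.n_samples
        target = plan.targets.get(spec)
        if target is None:
            raise ValueError(f"plan has no target for specimen {spec!r}")
        if target < n_real:
            raise ValueError(
                f"target {target} for group {key} smaller than real count {n_real}"
            )
        group_rng = np.random.default_rng(child_seeds[key])
        all_tables.append(g_table)
        all_meta.extend(g_meta)
        need = target - n_real
        if need == 0:
            continue
        if n_real < 2:
            raise ValueError(f"group {key} has {n_real} real samples; need >= 2 to fit")

        train_table = g_table
        if cond == "CRC" and n_real > plan.crc_training_subset_size:
            pick = np.sort(
                group_rng.choice(n_real, size=plan.crc_training_subset_size, replace=False)
            )
            train_table = g_table.select_samples([g_table.sample_ids[i] for i in pick])
        model = fit_copula(
            train_table,
            enforce_min_max=plan.enforce_min_max,
            enforce_rounding=plan.enforce_rounding,
        )

        produced = 0
        round_index = 1
        while produced < need:
            batch_n = min(n_real, need - produced)  # rounds of the real count; last truncated
            batch = sample_synthetic(
                model,
                batch_n,
                seed=int(group_rng.integers(0, 2**31)),
                condition=cond,
                specimen=spec,
                round_index=round_index,
            )
            all_tables.append(batch.table)
            for i, sid in enumerate(batch.table.sample_ids):
                all_meta.append(
                    SampleMeta(sid, f"synp_{cond}_{spec}_{round_index}_{i:03d}", cond, spec, "synthetic")
                )
            produced += batch_n
            round_index += 1

    combined_counts = np.vstack([t.counts for t in all_tables])
    combined_ids = [s for t in all_tables for s in t.sample_ids]
    combined = OtuTable(combined_ids, list(table.feature_ids), combined_counts)
    return combined, all_meta
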