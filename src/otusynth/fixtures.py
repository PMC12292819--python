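"""Seeded synthetic ground-truth OTU datasets.

The generator emulates a two-condition (AP vs CRC), three-specimen
(stool/biopsy/saliva) 16S OTU count table with the heavy tails and
sparsity typical of microbiome data, plus a configurable set of planted
differentially abundant taxa so every downstream stage can be exercised
against a known answer.

Count law (hurdle model): each entry is a structural zero with probability
``zero_inflation``; otherwise it is ``1 + Poisson(lam)`` where
``log lam = base_j + specimen_shift + patient_offset + eps`` with
``eps ~ N(0, dispersion^2)``. The hurdle construction pins the expected
zero fraction at exactly ``zero_inflation``, which keeps the sparsity knob
honest, while the log-normal latent gives the heavy upper tail. Planted
taxa have their latent mean multiplied by ``effect_size`` in the condition
they are enriched in (directions alternate between CRC and AP).

Specimens from the same (synthetic) patient share a latent offset, so the
intra-patient correlation that real repeated-specimen designs carry is
present and its consequences are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CONDITIONS, SPECIMENS, OtuTable, SampleMeta

__all__ = ["FixtureConfig", "FixtureTruth", "make_fixture", "degrade_to_noise"]

#: study-scale per-(condition, specimen) sample counts
DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("AP", "stool"): 9,
    ("AP", "biopsy"): 13,
    ("AP", "saliva"): 12,
    ("CRC", "stool"): 34,
    ("CRC", "biopsy"): 40,
    ("CRC", "saliva"): 40,
}


@dataclass
class FixtureConfig:
    seed: int
    n_features: int = 200
    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_planted: int = 10
    effect_size: float = 4.0
    zero_inflation: float = 0.3
    dispersion: float = 0.6
    specimen_shift: dict[str, float] = field(
        default_factory=lambda: {"stool": 0.0, "biopsy": -0.4, "saliva": 0.6}
    )
    base_log_mean: float = 1.5
    base_log_sd: float = 1.2
    patient_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError(
                f"n_planted={self.n_planted} exceeds n_features={self.n_features}"
            )
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")
        # accept "COND/SPEC" string keys (the YAML-friendly spelling)
        self.group_sizes = {
            (tuple(k.split("/")) if isinstance(k, str) else tuple(k)): v
            for k, v in self.group_sizes.items()
        }
        for key in self.group_sizes:
            cond, spec = key
            if cond not in CONDITIONS or spec not in SPECIMENS:
                raise ValueError(f"unknown group {key}")


@dataclass(frozen=True)
class FixtureTruth:
    """Identity and direction of the planted differential taxa."""

    planted_feature_ids: list[str]
    direction: dict[str, str]  # feature id -> condition it is enriched in


def _feature_ids(n: int) -> list[str]:
    # plausible lineage-string identifiers; opaque to the pipeline
    phyla = ["Firmicutes", "Bacteroidota", "Proteobacteria", "Actinobacteriota", "Fusobacteriota"]
    return [
        f"Bacteria;{phyla[j % len(phyla)]};Family_{j // 10:03d};Genus_{j:05d}"
        for j in range(n)
    ]


def make_fixture(config: FixtureConfig) -> tuple[OtuTable, list[SampleMeta], FixtureTruth]:
    """Generate a seeded fixture dataset with planted AP/CRC signal."""
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    feature_ids = _feature_ids(p)

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=p)
    # plant signal only in taxa abundant enough to carry it: a fold change
    # on a near-absent taxon would be an undetectable "ground truth"
    eligible = np.flatnonzero(base >= np.median(base))
    if len(eligible) < config.n_planted:
        eligible = np.argsort(base)[-config.n_planted:]
    planted_idx = np.sort(rng.choice(eligible, size=config.n_planted, replace=False))
    directions = {
        feature_ids[j]: ("CRC" if i % 2 == 0 else "AP")
        for i, j in enumerate(planted_idx)
    }
    log_effect = np.log(config.effect_size)

    # one latent offset per (condition, within-condition patient index):
    # sample i of every specimen belongs to patient i, so patients with
    # multiple specimens share the offset (intra-patient correlation).
    n_patients = {
        cond: max(
            (config.group_sizes.get((cond, s), 0) for s in SPECIMENS), default=0
        )
        for cond in CONDITIONS
    }
    patient_offsets = {
        cond: rng.normal(0.0, config.patient_sd, size=max(n, 1))
        for cond, n in n_patients.items()
    }

    sample_ids: list[str] = []
    meta: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    for cond in CONDITIONS:
        for spec in SPECIMENS:
            n_grp = config.group_sizes.get((cond, spec), 0)
            for i in range(n_grp):
                sid = f"{cond}_{spec}_{i:03d}"
                pid = f"{cond}p{i:03d}"
                log_lam = (
                    base
                    + config.specimen_shift.get(spec, 0.0)
                    + patient_offsets[cond][i]
                    + rng.normal(0.0, config.dispersion, size=p)
                )
                for j in planted_idx:
                    if directions[feature_ids[j]] == cond:
                        log_lam[j] += log_effect
                lam = np.exp(log_lam)
                counts = 1 + rng.poisson(lam)
                zero_mask = rng.random(p) < config.zero_inflation
                counts[zero_mask] = 0
                sample_ids.append(sid)
                meta.append(SampleMeta(sid, pid, cond, spec, "real"))
                rows.append(counts.astype(float))

    table = OtuTable(sample_ids, feature_ids, np.vstack(rows) if rows else np.empty((0, p)))
    truth = FixtureTruth([feature_ids[j] for j in planted_idx], directions)
    return table, meta, truth


def degrade_to_noise(table: OtuTable, seed: int) -> OtuTable:
    """Deliberately bad 'synthesizer': destroy structure, keep marginals.

    Entries are independently permuted within each column (killing
    inter-feature and inter-sample correlation) and jittered by +/-1
    (clipped at zero). Serves as the negative control for the quality gate.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    n = counts.shape[0]
    for j in range(counts.shape[1]):
        counts[:, j] = counts[rng.permutation(n), j]
    jitter = rng.integers(-1, 2, size=counts.shape)
    counts = np.clip(counts + jitter, 0, None)
    return OtuTable(
        [f"noise_{s}" for s in table.sample_ids], list(table.feature_ids), counts
    )
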