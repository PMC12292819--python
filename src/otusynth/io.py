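"""OTU table and sample metadata I/O.

Tables are exchanged as TSV with samples as rows and a leading
``sample_id`` column; the transposed (features-as-rows) dialect is accepted
via an ``orientation`` flag. Metadata travels in a companion TSV keyed by
``sample_id``. Feature identifiers are opaque taxonomy lineage strings and
are never parsed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("AP", "CRC")
SPECIMENS = ("stool", "biopsy", "saliva")
PROVENANCES = ("real", "synthetic")

__all__ = [
    "CONDITIONS",
    "SPECIMENS",
    "PROVENANCES",
    "ValidationError",
    "OtuTable",
    "SampleMeta",
    "read_otu_table",
    "read_sample_meta",
    "write_otu_table",
    "write_sample_meta",
    "partition",
]


class ValidationError(ValueError):
    """Raised when a table or metadata record violates an invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata record.

    ``condition`` is the clinical group (AP = adenomatous polyps,
    CRC = colorectal cancer); ``specimen`` is the sampling site.
    """

    sample_id: str
    patient_id: str
    condition: str
    specimen: str
    provenance: str = "real"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} for sample {self.sample_id!r} "
                f"not in {CONDITIONS}"
            )
        if self.specimen not in SPECIMENS:
            raise ValidationError(
                f"specimen {self.specimen!r} for sample {self.sample_id!r} "
                f"not in {SPECIMENS}"
            )
        if self.provenance not in PROVENANCES:
            raise ValidationError(
                f"provenance {self.provenance!r} for sample {self.sample_id!r} "
                f"not in {PROVENANCES}"
            )


@dataclass
class OtuTable:
    """Samples x taxa nonnegative count matrix with lineage-string ids."""

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_features)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, p = self.counts.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for axis_name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValidationError(f"duplicate {axis_name} id {dup!r}")
        if not np.all(np.isfinite(self.counts)):
            i, j = np.argwhere(~np.isfinite(self.counts))[0]
            raise ValidationError(
                f"non-finite count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count {self.counts[i, j]} at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.feature_ids), self.counts[rows])

    def select_features(self, feature_ids: Sequence[str]) -> "OtuTable":
        idx = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [idx[f] for f in feature_ids]
        return OtuTable(list(self.sample_ids), list(feature_ids), self.counts[:, cols])


def read_otu_table(
    path: str | Path,
    orientation: str = "samples",
    meta_path: str | Path | None = None,
) -> tuple[OtuTable, list[SampleMeta] | None]:
    """Read a TSV count table (and optionally its companion metadata).

    ``orientation="samples"`` means rows are samples (the package's native
    dialect); ``"features"`` accepts the transposed layout.
    """
    if orientation not in ("samples", "features"):
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except OSError as exc:
        raise OSError(f"cannot read OTU table at {path}: {exc}") from exc
    if orientation == "features":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy()
    if pd.isna(values).any():
        i, j = np.argwhere(pd.isna(values))[0]
        raise ValidationError(
            f"missing/ragged value at sample {df.index[i]!r}, feature {df.columns[j]!r} in {path}"
        )
    table = OtuTable(list(df.index), list(df.columns), values.astype(float))
    meta = read_sample_meta(meta_path) if meta_path is not None else None
    if meta is not None:
        _check_meta_cover(table, meta)
    return table, meta


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "condition", "specimen"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata file {path} missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleMeta(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                condition=row.condition,
                specimen=row.specimen,
                provenance=getattr(row, "provenance", "real") or "real",
            )
        )
    ids = [m.sample_id for m in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate sample_id in metadata file {path}")
    return records


def _check_meta_cover(table: OtuTable, meta: Sequence[SampleMeta]) -> None:
    by_id = {m.sample_id for m in meta}
    for s in table.sample_ids:
        if s not in by_id:
            raise ValidationError(f"sample {s!r} has no metadata record")


def write_otu_table(
    table: OtuTable,
    path: str | Path,
    meta: Sequence[SampleMeta] | None = None,
    meta_path: str | Path | None = None,
) -> None:
    """Write the table (samples as rows) as TSV; deterministic column order.

    Lineage ids containing tabs/quotes are CSV-quoted so the file
    round-trips through :func:`read_otu_table`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.to_dataframe()
    # integer-valued matrices are written without a decimal point
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.astype(np.int64)
    try:
        df.to_csv(path, sep="\t", quoting=csv.QUOTE_MINIMAL)
    except OSError as exc:
        raise OSError(f"cannot write OTU table to {path}: {exc}") from exc
    if meta is not None:
        write_sample_meta(meta, meta_path or path.with_suffix(".meta.tsv"))


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.sample_id, m.patient_id, m.condition, m.specimen, m.provenance)
            for m in meta
        ],
        columns=["sample_id", "patient_id", "condition", "specimen", "provenance"],
    )
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_MINIMAL)


_GROUP_KEYS = ("condition", "specimen", "provenance")


def partition(
    table: OtuTable,
    meta: Sequence[SampleMeta],
    by: Iterable[str] = (),
) -> dict[tuple, tuple[OtuTable, list[SampleMeta]]]:
    """Partition samples into disjoint groups keyed by metadata fields.

    ``by`` is a subset of {condition, specimen, provenance}. The returned
    groups are pairwise disjoint and their union is the input table; the
    feature axis is unchanged. An empty ``by`` yields a single group keyed
    by the empty tuple.
    """
    by = tuple(by)
    for key in by:
        if key not in _GROUP_KEYS:
            raise ValueError(f"unknown grouping key {key!r}; expected subset of {_GROUP_KEYS}")
    _check_meta_cover(table, meta)
    meta_by_id: Mapping[str, SampleMeta] = {m.sample_id: m for m in meta}
    groups: dict[tuple, list[str]] = {}
    for s in table.sample_ids:
        m = meta_by_id[s]
        key = tuple(getattr(m, k) for k in by)
        groups.setdefault(key, []).append(s)
    return {
        key: (table.select_samples(ids), [meta_by_id[s] for s in ids])
        for key, ids in groups.items()
    }
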