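"""Beta diversity: sqrt percent-abundance transform, Bray-Curtis, PCoA.

Bray-Curtis is a semimetric (the triangle inequality can fail), so its
PCoA generally produces negative eigenvalues; those are reported, excluded
from the coordinates, and the explained proportions are taken over the
positive spectrum only. Axis signs follow a deterministic convention (the
largest-magnitude loading of each axis is positive) so ordinations are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "sqrt_percent_abundance",
    "bray_curtis_matrix",
    "pcoa",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.data, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if D.shape[0] != len(self.sample_ids):
            raise ValueError("sample ids do not match matrix dimension")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        self.data = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # full spectrum, descending
    proportion_explained: np.ndarray  # per positive axis, over positive spectrum
    n_negative_eigenvalues: int
    sum_negative_eigenvalues: float

    def to_frame(self, axes: int = 2) -> pd.DataFrame:
        k = min(axes, self.coordinates.shape[1])
        return pd.DataFrame(
            self.coordinates[:, :k],
            index=self.sample_ids,
            columns=[f"PC{i + 1}" for i in range(k)],
        )


def sqrt_percent_abundance(table: OtuTable | np.ndarray) -> np.ndarray:
    """Per sample: count -> sqrt(100 * count / row total).

    Squared row sums equal 100, so the transform is invariant to sample
    sequencing depth. All-zero samples are rejected by name.
    """
    if isinstance(table, OtuTable):
        X = table.counts
        ids = table.sample_ids
    else:
        X = np.asarray(table, dtype=float)
        ids = [str(i) for i in range(len(X))]
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return np.sqrt(100.0 * X / totals[:, None])


def bray_curtis_matrix(
    matrix: np.ndarray, sample_ids: list[str] | None = None
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|u-v| / sum(u+v), in [0, 1].

    A pair of all-zero rows gets distance 0 by convention.
    """
    X = np.asarray(matrix, dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i + 1 :] - X[i]).sum(axis=1)
        den = (X[i + 1 :] + X[i]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, num / den, 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(list(sample_ids), D)


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal Coordinate Analysis by Gower double-centering.

    G = -1/2 * J D^2 J with J = I - 11'/n; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for eigenvalues above a relative tolerance.
    """
    D = dist.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = 0.5 * (G + G.T)
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(np.abs(w).max(), 1.0) * 1e-12 if n else 0.0
    pos = w > tol
    coords = V[:, pos] * np.sqrt(w[pos])
    # deterministic sign: largest-|loading| entry of each axis positive
    for a in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, a])))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    pos_sum = w[pos].sum()
    proportions = w[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    neg = w < -tol
    return PcoaResult(
        sample_ids=list(dist.sample_ids),
        coordinates=coords,
        eigenvalues=w,
        proportion_explained=proportions,
        n_negative_eigenvalues=int(neg.sum()),
        sum_negative_eigenvalues=float(w[neg].sum()),
    )
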