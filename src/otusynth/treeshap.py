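"""Exact path-dependent TreeSHAP for xgboost boosters, in float64.

Computes per-feature Shapley values of a gradient-boosted tree ensemble's
margin output, distributing each tree's prediction over the features on
its decision paths with the tree's training cover as the background
weighting. All arithmetic is double precision over the dumped tree
structure, so the additivity identity

    base_value + sum_j phi_j = margin(x)

holds to float64 round-off (the margin is likewise re-evaluated from the
dumped trees).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["parse_booster", "tree_shap_values", "TreeEnsemble"]


@dataclass
class _Tree:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray  # -1 for leaves
    threshold: np.ndarray
    value: np.ndarray  # leaf value (0 for internal)
    cover: np.ndarray


@dataclass
class TreeEnsemble:
    trees: list[_Tree]
    base_offset: float  # global margin offset (e.g. logit of base_score)

    @property
    def expected_value(self) -> float:
        ev = self.base_offset
        for t in self.trees:
            ev += _tree_expected(t, 0)
        return ev

    def margin(self, X: np.ndarray) -> np.ndarray:
        # xgboost routes with float32 comparisons; mirror that exactly
        X = np.atleast_2d(np.asarray(X, dtype=np.float32)).astype(float)
        out = np.full(len(X), self.base_offset)
        for t in self.trees:
            for i, x in enumerate(X):
                j = 0
                while t.feature[j] >= 0:
                    j = (
                        t.children_left[j]
                        if x[t.feature[j]] < t.threshold[j]
                        else t.children_right[j]
                    )
                out[i] += t.value[j]
        return out


def _tree_expected(t: _Tree, j: int) -> float:
    if t.feature[j] < 0:
        return t.value[j]
    l, r = t.children_left[j], t.children_right[j]
    return (
        t.cover[l] * _tree_expected(t, l) + t.cover[r] * _tree_expected(t, r)
    ) / t.cover[j]


def _flatten(node: dict, store: dict[int, dict]) -> None:
    store[node["nodeid"]] = node
    for child in node.get("children", ()):
        _flatten(child, store)


def parse_booster(booster, n_features: int) -> TreeEnsemble:
    """Extract tree arrays from an xgboost booster (json dump with stats)."""
    dumps = booster.get_dump(with_stats=True, dump_format="json")
    trees = []
    for d in dumps:
        nodes: dict[int, dict] = {}
        _flatten(json.loads(d), nodes)
        n = max(nodes) + 1
        t = _Tree(
            children_left=np.full(n, -1, dtype=int),
            children_right=np.full(n, -1, dtype=int),
            feature=np.full(n, -1, dtype=int),
            threshold=np.zeros(n),
            value=np.zeros(n),
            cover=np.zeros(n),
        )
        for nid, node in nodes.items():
            t.cover[nid] = node["cover"]
            if "leaf" in node:
                t.value[nid] = node["leaf"]
            else:
                feat = node["split"]
                t.feature[nid] = int(feat[1:]) if feat.startswith("f") else int(feat)
                # thresholds are float32 in the booster; keep them exact
                t.threshold[nid] = float(np.float32(node["split_condition"]))
                t.children_left[nid] = node["yes"]
                t.children_right[nid] = node["no"]
        trees.append(t)
    return TreeEnsemble(trees, base_offset=0.0)


# --- the polynomial-time path algorithm ------------------------------------


def _extend(d, z, o, w, length, pd, pz, po):
    d[length] = pd
    z[length] = pz
    o[length] = po
    w[length] = 1.0 if length == 0 else 0.0
    l = length + 1
    for i in range(length - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / l
        w[i] = pz * w[i] * (l - i - 1) / l


def _unwind(d, z, o, w, length, i):
    l = length + 1
    one, zero = o[i], z[i]
    n = w[length]
    for j in range(length - 1, -1, -1):
        if one != 0:
            t = w[j]
            w[j] = n * l / ((j + 1) * one)
            n = t - w[j] * zero * (l - j - 1) / l
        else:
            w[j] = w[j] * l / (zero * (l - j - 1))
    for j in range(i, length):
        d[j] = d[j + 1]
        z[j] = z[j + 1]
        o[j] = o[j + 1]


def _unwound_sum(z, o, w, length, i):
    l = length + 1
    one, zero = o[i], z[i]
    total = 0.0
    n = w[length]
    for j in range(length - 1, -1, -1):
        if one != 0:
            t = n * l / ((j + 1) * one)
            total += t
            n = w[j] - t * zero * (l - j - 1) / l
        else:
            total += w[j] * l / (zero * (l - j - 1))
    return total


def _tree_shap(t: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    max_depth = 0

    def depth(j, dep):
        nonlocal max_depth
        max_depth = max(max_depth, dep)
        if t.feature[j] >= 0:
            depth(t.children_left[j], dep + 1)
            depth(t.children_right[j], dep + 1)

    depth(0, 0)
    size = max_depth + 2

    def recurse(j, d, z, o, w, length, pz, po, pd):
        d, z, o, w = d.copy(), z.copy(), o.copy(), w.copy()
        _extend(d, z, o, w, length, pd, pz, po)
        length += 1
        if t.feature[j] < 0:
            for i in range(1, length):
                scale = _unwound_sum(z, o, w, length - 1, i)
                phi[int(d[i])] += scale * (o[i] - z[i]) * t.value[j]
            return
        hot = (
            t.children_left[j]
            if x[t.feature[j]] < t.threshold[j]
            else t.children_right[j]
        )
        cold = (
            t.children_right[j] if hot == t.children_left[j] else t.children_left[j]
        )
        iz, io = 1.0, 1.0
        k = next(
            (i for i in range(1, length) if int(d[i]) == t.feature[j]), -1
        )
        if k >= 0:
            iz, io = z[k], o[k]
            _unwind(d, z, o, w, length - 1, k)
            length -= 1
        recurse(hot, d, z, o, w, length, iz * t.cover[hot] / t.cover[j], io, t.feature[j])
        recurse(cold, d, z, o, w, length, iz * t.cover[cold] / t.cover[j], 0.0, t.feature[j])

    d = np.zeros(size)
    z = np.zeros(size)
    o = np.zeros(size)
    w = np.zeros(size)
    recurse(0, d, z, o, w, 0, 1.0, 1.0, -1)


def tree_shap_values(ensemble: TreeEnsemble, X: np.ndarray, n_features: int) -> np.ndarray:
    """Shapley values per sample, shape (n_samples, n_features)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float32)).astype(float)
    phi = np.zeros((len(X), n_features))
    for i, x in enumerate(X):
        for t in ensemble.trees:
            _tree_shap(t, x, phi[i])
    return phi
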