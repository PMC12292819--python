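"""Small dense network for binary AP/CRC classification.

Architecture: Dense(64) -> Dense(32) -> Dense(1, sigmoid), hidden
activation selectable among ReLU, LeakyReLU(alpha=0.01), Softmax (vector
softmax over the layer's units) and GeLU; adam optimizer; binary
cross-entropy loss; batch size 32; 45 epochs. Implemented directly in
numpy so layer weights and activations are available to the relevance
propagation in :mod:`otusynth.lrp`, and so training is single-threaded
deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, expit

__all__ = ["DenseNetSpec", "DenseNet", "train_dense_net", "ACTIVATIONS"]


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0).astype(float)


def _leaky_relu(z: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    return np.where(z > 0, z, alpha * z)


def _leaky_relu_grad(z: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    return np.where(z > 0, 1.0, alpha)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _gelu(z: np.ndarray) -> np.ndarray:
    return 0.5 * z * (1.0 + erf(z / np.sqrt(2.0)))


def _gelu_grad(z: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi)
    return 0.5 * (1.0 + erf(z / np.sqrt(2.0))) + z * phi


ACTIVATIONS = ("relu", "leaky_relu", "softmax", "gelu")


@dataclass(frozen=True)
class DenseNetSpec:
    hidden_widths: tuple[int, ...] = (64, 32)
    activation: str = "leaky_relu"
    leaky_alpha: float = 0.01
    epochs: int = 45
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation {self.activation!r} not in {ACTIVATIONS}")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("layer widths must be positive")


class DenseNet:
    """Trained dense network: weight/bias lists plus training history."""

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray], spec: DenseNetSpec):
        self.weights = weights  # W[l] has shape (d_in, d_out)
        self.biases = biases
        self.spec = spec
        self.history: dict[str, list[float]] = {"loss": [], "accuracy": []}

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def _activate(self, z: np.ndarray) -> np.ndarray:
        act = self.spec.activation
        if act == "relu":
            return _relu(z)
        if act == "leaky_relu":
            return _leaky_relu(z, self.spec.leaky_alpha)
        if act == "softmax":
            return _softmax(z)
        return _gelu(z)

    def _activate_grad(self, z: np.ndarray, a: np.ndarray) -> np.ndarray | None:
        """Elementwise activation derivative; None signals full-Jacobian (softmax)."""
        act = self.spec.activation
        if act == "relu":
            return _relu_grad(z)
        if act == "leaky_relu":
            return _leaky_relu_grad(z, self.spec.leaky_alpha)
        if act == "gelu":
            return _gelu_grad(z)
        return None

    def forward_cached(self, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """Return (activations, pre-activations) per layer.

        ``activations[0]`` is the input; ``pre_acts[l]`` is the affine
        output of layer ``l``; the final layer's activation is the raw
        logit (sigmoid applied separately).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acts = [X]
        zs = []
        a = X
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            zs.append(z)
            a = z if l == self.n_layers - 1 else self._activate(z)
            acts.append(a)
        return acts, zs

    def logits(self, X: np.ndarray) -> np.ndarray:
        acts, _ = self.forward_cached(X)
        return acts[-1][:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.logits(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def train_dense_net(X: np.ndarray, labels: np.ndarray, spec: DenseNetSpec) -> DenseNet:
    """Train the network with adam on binary cross-entropy.

    Labels must be binary {0, 1} with both classes present. Raises on
    NaN loss with the offending epoch index. Same spec and data => same
    final weights (single-threaded numpy determinism).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"labels must be binary 0/1, got values {uniq}")
    if len(uniq) < 2:
        raise ValueError("labels are constant; need both classes")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    rng = np.random.default_rng(spec.seed)
    widths = (X.shape[1],) + tuple(spec.hidden_widths) + (1,)
    weights, biases = [], []
    for d_in, d_out in zip(widths[:-1], widths[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))  # Glorot-uniform
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    net = DenseNet(weights, biases, spec)

    m = [np.zeros_like(w) for w in weights] + [np.zeros_like(b) for b in biases]
    v = [np.zeros_like(g) for g in m]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(X)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = X[idx], y[idx]
            acts, zs = net.forward_cached(xb)
            logit = acts[-1][:, 0]
            prob = expit(logit)
            p = np.clip(prob, 1e-12, 1 - 1e-12)
            loss = -np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p))
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}")
            epoch_loss += loss * len(idx)

            grads_w = [np.zeros_like(w) for w in net.weights]
            grads_b = [np.zeros_like(b) for b in net.biases]
            # dL/dlogit for sigmoid+BCE
            delta = ((prob - yb) / len(idx))[:, None]
            for l in range(net.n_layers - 1, -1, -1):
                a_in = acts[l]
                grads_w[l] = a_in.T @ delta
                grads_b[l] = delta.sum(axis=0)
                if l > 0:
                    delta = delta @ net.weights[l].T
                    g = net._activate_grad(zs[l - 1], acts[l])
                    if g is not None:
                        delta = delta * g
                    else:  # softmax full Jacobian, row-wise
                        s = acts[l]
                        delta = s * (delta - (delta * s).sum(axis=1, keepdims=True))

            t += 1
            params = net.weights + net.biases
            grads = grads_w + grads_b
            lr_t = spec.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for i, (param, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                param -= lr_t * m[i] / (np.sqrt(v[i]) + eps)

        train_acc = float(np.mean(net.predict(X) == y))
        net.history["loss"].append(float(epoch_loss / n))
        net.history["accuracy"].append(train_acc)
    return net
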