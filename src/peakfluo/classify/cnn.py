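"""A small convolutional network in pure NumPy.

The environment ships no deep-learning framework, so the six-layer
architecture — conv, max-pool, conv, max-pool, flatten, dense — is
implemented directly: im2col convolutions, 2x2 max pooling, a single
sigmoid output unit trained with binary cross-entropy and Adam.  Everything
is seeded, so construction and training are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["CNNClassifier", "build_cnn"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H-k+1, W-k+1, C*k*k) sliding windows."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    n, oh, ow = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, oh, ow, -1)


class _Conv:
    kind = "conv"

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.kernel = kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters))
        self.b = np.zeros(filters)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        self._cols = _im2col(x, self.kernel)
        pre = self._cols @ self.w + self.b
        self._mask = pre > 0
        return np.where(self._mask, pre, 0.0)

    def backward(self, grad: np.ndarray):
        grad = grad * self._mask
        n, oh, ow, f = grad.shape
        g2 = grad.reshape(-1, f)
        self.dw = self._cols.reshape(-1, self.w.shape[0]).T @ g2
        self.db = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(n, oh, ow, -1)
        nh, nw, c = self._in_shape[1], self._in_shape[2], self._in_shape[3]
        k = self.kernel
        dcols = dcols.reshape(n, oh, ow, c, k, k)
        dx = np.zeros(self._in_shape)
        for i in range(k):
            for j in range(k):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, :, i, j]
        return dx

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _MaxPool:
    kind = "maxpool"

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.size
        n, h, w, c = x.shape
        oh, ow = h // s, w // s
        self._in_shape = x.shape
        xc = x[:, : oh * s, : ow * s, :]
        win = xc.reshape(n, oh, s, ow, s, c).transpose(0, 1, 3, 5, 2, 4)
        flat = win.reshape(n, oh, ow, c, s * s)
        self._arg = np.argmax(flat, axis=-1)
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray):
        s = self.size
        n, oh, ow, c = grad.shape
        flat = np.zeros((n, oh, ow, c, s * s))
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        win = flat.reshape(n, oh, ow, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape)
        dx[:, : oh * s, : ow * s, :] = win.reshape(n, oh * s, ow * s, c)
        return dx

    def params(self):
        return []


class _Flatten:
    kind = "flatten"

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray):
        return grad.reshape(self._in_shape)

    def params(self):
        return []


class _Dense:
    kind = "dense"

    def __init__(self, in_dim: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(1.0 / in_dim), size=(in_dim, 1))
        self.b = np.zeros(1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray):
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


@dataclass
class _Adam:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    state: dict = field(default_factory=dict)

    def step(self, layers: Sequence) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            for name, param, gname in layer.params():
                g = getattr(layer, gname)
                key = (li, name)
                m, v = self.state.get(key, (np.zeros_like(param), np.zeros_like(param)))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                self.state[key] = (m, v)
                mh = m / (1 - self.beta1**self.t)
                vh = v / (1 - self.beta2**self.t)
                param -= self.lr * mh / (np.sqrt(vh) + self.eps)


class CNNClassifier:
    """conv -> maxpool -> conv -> maxpool -> flatten -> dense(1, sigmoid)."""

    def __init__(
        self,
        input_shape: tuple[int, int],
        conv1_filters: int = 16,
        conv2_filters: int = 32,
        kernel: int = 3,
        seed: int = 0,
    ):
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        h, w = self.input_shape
        c1 = _Conv(1, conv1_filters, kernel, rng)
        p1 = _MaxPool(2)
        h1, w1 = (h - kernel + 1) // 2, (w - kernel + 1) // 2
        c2 = _Conv(conv1_filters, conv2_filters, kernel, rng)
        p2 = _MaxPool(2)
        h2, w2 = (h1 - kernel + 1) // 2, (w1 - kernel + 1) // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(f"input shape {input_shape} too small for the architecture")
        flat_dim = h2 * w2 * conv2_filters
        self.layers = [c1, p1, c2, p2, _Flatten(), _Dense(flat_dim, rng)]

    @property
    def layer_types(self) -> list[str]:
        return [layer.kind for layer in self.layers]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for _, p, _ in layer.params())

    def _forward(self, x: np.ndarray) -> np.ndarray:
        out = x[..., None].astype(float) if x.ndim == 3 else x.astype(float)
        for layer in self.layers:
            out = layer.forward(out)
        return out[:, 0]  # logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = [
            _sigmoid(self._forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(probs) if probs else np.empty(0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(np.int8)

    @staticmethod
    def _bce(probs: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(probs, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(loss, accuracy) on a labeled set."""
        probs = self.predict_proba(x)
        acc = float(np.mean((probs >= 0.5).astype(int) == y))
        return self._bce(probs, y), acc

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 20,
        batch_size: int = 32,
        lr: float = 1e-3,
        val_fraction: float = 0.1,
        patience: int = 4,
        seed: int | None = None,
        verbose: bool = False,
    ) -> dict:
        """Mini-batch Adam on binary cross-entropy with early stopping on an
        internal validation split; best-epoch weights are restored."""
        if len(x) == 0:
            raise ValueError("cannot train on an empty dataset")
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        order = rng.permutation(len(x))
        n_val = max(1, int(round(val_fraction * len(x)))) if val_fraction > 0 else 0
        val_idx, train_idx = order[:n_val], order[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = order, order[:0]
        xt, yt = x[train_idx], y[train_idx]
        opt = _Adam(lr=lr)
        best_loss, best_state, wait = np.inf, None, 0
        history: dict[str, list[float]] = {"loss": [], "val_loss": []}
        for epoch in range(epochs):
            perm = rng.permutation(len(xt))
            for i in range(0, len(xt), batch_size):
                idx = perm[i : i + batch_size]
                xb, yb = xt[idx], yt[idx]
                logits = self._forward(xb)
                probs = _sigmoid(logits)
                grad = ((probs - yb) / len(yb))[:, None]
                upstream = grad
                for layer in reversed(self.layers):
                    upstream = layer.backward(upstream)
                opt.step(self.layers)
            train_loss, _ = self.evaluate(xt, yt)
            history["loss"].append(train_loss)
            if n_val:
                val_loss, _ = self.evaluate(x[val_idx], y[val_idx])
            else:
                val_loss = train_loss
            history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch + 1}: loss={train_loss:.4f} val={val_loss:.4f}")
            if val_loss < best_loss - 1e-6:
                best_loss, wait = val_loss, 0
                best_state = self.get_weights()
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_state is not None:
            self.set_weights(best_state)
        return history

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                out[f"{li}.{name}"] = param.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                param[...] = weights[f"{li}.{name}"]


def build_cnn(
    input_shape: tuple[int, int],
    conv1_filters: int = 16,
    conv2_filters: int = 32,
    kernel: int = 3,
    seed: int = 0,
) -> CNNClassifier:
    """Construct the six-layer network for grayscale images of ``input_shape``."""
    return CNNClassifier(input_shape, conv1_filters, conv2_filters, kernel, seed)
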