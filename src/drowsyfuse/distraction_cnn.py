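"""Image CNN for distraction-style classification, in pure numpy.

Fixed architecture: three valid 3x3 convolution layers of 32/64/128
filters with ReLU, max-pooling (2x2, stride 2) after the first two,
flatten, dense layers of 128 and 64 ReLU units, and a softmax output
layer of 192 units by default (configurable). Training uses the Adam
optimizer with sparse categorical cross-entropy, deterministic given
the seed.

A hand-rolled implementation is used because no deep-learning framework
is available in the runtime; the network is small enough that batched
matmul convolutions are fast at fixture scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class CNNSpec:
    """Architecture description. ``conv_blocks`` entries are
    (filters, kernel_size, followed_by_maxpool)."""

    conv_blocks: Tuple[Tuple[int, int, bool], ...] = (
        (32, 3, True),
        (64, 3, True),
        (128, 3, False),
    )
    dense: Tuple[int, ...] = (128, 64)
    output_units: int = 192
    input_size: Tuple[int, int, int] = (64, 64, 3)

    def __post_init__(self) -> None:
        if self.output_units < 2:
            raise ValueError("output_units must be >= 2")
        h, w, _ = self.input_size
        if h < 16 or w < 16:
            raise ValueError("input_size must be at least 16x16")


class _Conv:
    def __init__(self, rng, k: int, c_in: int, c_out: int):
        scale = np.sqrt(2.0 / (k * k * c_in))  # He init for ReLU
        self.W = rng.standard_normal((k, k, c_in, c_out)) * scale
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, _ = x.shape
        k = self.k
        oh, ow = h - k + 1, w - k + 1
        if oh < 1 or ow < 1:
            raise ValueError("feature map collapsed: input too small")
        out = np.tile(self.b, (n, oh, ow, 1))
        for i in range(k):
            for j in range(k):
                out += x[:, i : i + oh, j : j + ow, :] @ self.W[i, j]
        self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, k = self._x, self.k
        n, oh, ow, _ = dout.shape
        self.dW = np.empty_like(self.W)
        dx = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                patch = x[:, i : i + oh, j : j + ow, :]
                self.dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, i : i + oh, j : j + ow, :] += dout @ self.W[i, j].T
        self.db = dout.sum(axis=(0, 1, 2))
        return dx

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _MaxPool:
    """2x2 max pooling, stride 2; odd trailing rows/cols dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xr = (
            x[:, : 2 * h2, : 2 * w2, :]
            .reshape(n, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, h2, w2, 4, c)
        )
        self._idx = xr.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, h2, w2, 4, c))
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros((n, h, w, c))
        dx[:, : 2 * h2, : 2 * w2, :] = (
            dxr.reshape(n, h2, w2, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, 2 * h2, 2 * w2, c)
        )
        return dx

    def params(self):
        return []


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNModel:
    """Built network: ordered layers plus an architecture summary."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        h, w, c = spec.input_size
        self.layers: List = []
        self._summary: List[Dict] = []

        def note(name, shape, n_params):
            self._summary.append(
                {"layer": name, "output_shape": tuple(shape), "params": int(n_params)}
            )

        for filters, k, pool in spec.conv_blocks:
            conv = _Conv(rng, k, c, filters)
            self.layers += [conv, _ReLU()]
            h, w, c = h - k + 1, w - k + 1, filters
            if h < 1 or w < 1:
                raise ValueError("input too small for the convolution stack")
            note(f"conv{k}x{k}_{filters}_relu", (h, w, c), conv.W.size + filters)
            if pool:
                self.layers.append(_MaxPool())
                h, w = h // 2, w // 2
                if h < 1 or w < 1:
                    raise ValueError("input too small for two poolings")
                note("maxpool2x2", (h, w, c), 0)
        self.layers.append(_Flatten())
        n_in = h * w * c
        note("flatten", (n_in,), 0)
        for units in spec.dense:
            dense = _Dense(rng, n_in, units)
            self.layers += [dense, _ReLU()]
            note(f"dense_{units}_relu", (units,), dense.W.size + units)
            n_in = units
        out = _Dense(rng, n_in, spec.output_units)
        self.layers.append(out)
        note(f"dense_{spec.output_units}_softmax",
             (spec.output_units,), out.W.size + spec.output_units)

    def summary(self) -> List[Dict]:
        return [dict(row) for row in self._summary]

    @property
    def output_units(self) -> int:
        return self._summary[-1]["output_shape"][0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a batch (n, H, W, C) in [0, 1]."""
        h = np.asarray(x, dtype=float)
        if h.shape[1:] != self.spec.input_size:
            raise ValueError(
                f"input shape {h.shape[1:]} != spec {self.spec.input_size}"
            )
        for layer in self.layers:
            h = layer.forward(h)
        return _softmax(h)

    def _backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def trainable(self):
        for layer in self.layers:
            for param, gname in layer.params():
                yield layer, param, gname


class _Adam:
    def __init__(self, model: CNNModel, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model, self.lr, self.b1, self.b2, self.eps = model, lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, p, _ in model.trainable()]
        self.v = [np.zeros_like(p) for _, p, _ in model.trainable()]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, param, gname) in enumerate(self.model.trainable()):
            g = getattr(layer, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_model(spec: Optional[CNNSpec] = None, seed: int = 0) -> CNNModel:
    """Construct the network and its layer-by-layer summary."""
    return CNNModel(spec or CNNSpec(), seed)


def train_cnn(
    images: np.ndarray,
    labels: Sequence[int],
    spec: Optional[CNNSpec] = None,
    epochs: int = 20,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 16,
) -> Tuple[CNNModel, Dict[str, List[float]]]:
    """Train on uint8/float images; returns (model, per-epoch history).

    Loss is sparse categorical cross-entropy; history records mean loss
    and training accuracy per epoch.
    """
    labels = np.asarray(labels, dtype=int)
    spec = spec or CNNSpec()
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    if labels.max() >= spec.output_units or labels.min() < 0:
        raise ValueError("labels must lie in [0, output_units)")
    x = np.asarray(images, dtype=float)
    if x.max() > 1.5:
        x = x / 255.0
    model = CNNModel(spec, seed)
    opt = _Adam(model, lr=lr)
    rng = np.random.default_rng(seed)
    n = len(x)
    history: Dict[str, List[float]] = {"loss": [], "accuracy": []}
    for _ in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], labels[idx]
            probs = model.forward(xb)
            p_true = np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)
            losses.append(float(-np.mean(np.log(p_true))))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grad = probs.copy()
            grad[np.arange(len(yb)), yb] -= 1.0
            model._backward(grad / len(yb))
            opt.step()
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)
    return model, history


def predict_image(
    model: CNNModel, images: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Argmax class labels and softmax probabilities for a batch."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[None, ...]
    if x.max() > 1.5:
        x = x / 255.0
    probs = model.forward(x)
    return probs.argmax(axis=1), probs
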