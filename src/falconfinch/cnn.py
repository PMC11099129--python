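"""Compact CNN classifier with an optimizer-tuned output layer.

The canonical architecture takes a 22x11x1 feature plane through three
conv(3x3, same, relu) + shape-preserving maxpool blocks (16/32/64 filters),
dropout, flatten (15,488), a dense relu layer of 64 units and a dense
softmax head of 2 units. It is trained with Adam on a mean-squared-error
loss over the softmax probabilities, and the 130 weights+biases of the
final head can additionally be tuned by the falcon finch optimizer against
a held-out fold.

All layers (forward and backward) are implemented in NumPy; at this input
size a full training run is seconds on one CPU. Max-pooling uses pool 2,
stride 1 and same padding, which preserves the spatial shape.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from falconfinch import ffo as _ffo
from falconfinch.features import FeatureVector

logger = logging.getLogger(__name__)

INPUT_SHAPE = (22, 11, 1)
PLANE_SIZE = INPUT_SHAPE[0] * INPUT_SHAPE[1]  # 242


# ---------------------------------------------------------------------------
# declarative spec


@dataclass
class LayerSpec:
    kind: str  # conv | maxpool | dropout | flatten | dense
    filters: int = 0  # conv filters or dense units
    kernel: tuple[int, int] = (3, 3)
    activation: str = "none"  # relu | softmax | none
    rate: float = 0.0  # dropout rate

    def validate(self) -> None:
        if self.kind not in ("conv", "maxpool", "dropout", "flatten", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "dense") and self.filters <= 0:
            raise ValueError(f"{self.kind} layer needs positive filters/units")
        if not 0.0 <= self.rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")


@dataclass
class NetworkSpec:
    layers: list[LayerSpec]
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    loss: str = "mse"
    optimizer: str = "adam"
    batch_size: int = 32
    epochs: int = 100
    # 1e-4: with the 15,488-wide flatten feeding the first dense layer,
    # Adam's per-parameter steps shift that layer's outputs coherently, and
    # larger rates saturate the softmax within a few batches.
    learning_rate: float = 1e-4

    def validate(self) -> None:
        for lay in self.layers:
            lay.validate()
        last = self.layers[-1]
        if not (last.kind == "dense" and last.filters == 2 and last.activation == "softmax"):
            raise ValueError("last layer must be dense(2, softmax)")

    def to_manifest(self, path) -> None:
        per_layer, total, shapes = count_parameters(self)
        payload = {
            "spec": asdict(self),
            "per_layer_parameters": per_layer,
            "total_parameters": total,
            "output_shapes": [list(s) for s in shapes],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def canonical_spec() -> NetworkSpec:
    """The reference architecture (22x11x1 input, dense(2, softmax) head)."""
    return NetworkSpec(
        layers=[
            LayerSpec("conv", 16, (3, 3), "relu"),
            LayerSpec("maxpool"),
            LayerSpec("conv", 32, (3, 3), "relu"),
            LayerSpec("maxpool"),
            LayerSpec("conv", 64, (3, 3), "relu"),
            LayerSpec("maxpool"),
            LayerSpec("dropout", rate=0.25),
            LayerSpec("flatten"),
            LayerSpec("dense", 64, activation="relu"),
            LayerSpec("dense", 2, activation="softmax"),
        ]
    )


def count_parameters(spec: NetworkSpec) -> tuple[list[int], int, list[tuple]]:
    """Propagate shapes and count trainable parameters per layer.

    Returns (per-layer counts, total, per-layer output shapes). Conv layers
    contribute ``kh*kw*C_in*filters + filters``; dense ``in*units + units``;
    pooling/dropout/flatten contribute nothing.
    """
    shape: tuple = tuple(spec.input_shape)
    counts, shapes = [], []
    for idx, lay in enumerate(spec.layers):
        lay.validate()
        if lay.kind == "conv":
            if len(shape) != 3:
                raise ValueError(f"layer {idx} (conv) expects a 3-d input, got {shape}")
            kh, kw = lay.kernel
            counts.append(kh * kw * shape[2] * lay.filters + lay.filters)
            shape = (shape[0], shape[1], lay.filters)
        elif lay.kind in ("maxpool", "dropout"):
            counts.append(0)
        elif lay.kind == "flatten":
            counts.append(0)
            shape = (int(np.prod(shape)),)
        elif lay.kind == "dense":
            if len(shape) != 1:
                raise ValueError(f"layer {idx} (dense) expects a flat input, got {shape}")
            counts.append(shape[0] * lay.filters + lay.filters)
            shape = (lay.filters,)
        shapes.append(shape)
    return counts, int(sum(counts)), shapes


# ---------------------------------------------------------------------------
# numpy layers


def _conv_forward(x, w, b):
    n, h, wd, _ = x.shape
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.zeros((n, h, wd, w.shape[3]))
    for dy in range(kh):
        for dx in range(kw):
            out += np.tensordot(xp[:, dy : dy + h, dx : dx + wd, :], w[dy, dx], axes=([3], [0]))
    return out + b, xp


def _conv_backward(dout, xp, w):
    n, h, wd, _ = dout.shape
    kh, kw = w.shape[:2]
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for dy in range(kh):
        for dx in range(kw):
            patch = xp[:, dy : dy + h, dx : dx + wd, :]
            dw[dy, dx] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, dy : dy + h, dx : dx + wd, :] += dout @ w[dy, dx].T
    db = dout.sum(axis=(0, 1, 2))
    ph, pw = kh // 2, kw // 2
    hx, wx = xp.shape[1] - 2 * ph, xp.shape[2] - 2 * pw
    return dxp[:, ph : ph + hx, pw : pw + wx, :], dw, db


_POOL_OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))


def _maxpool_forward(x):
    # pool 2, stride 1, same padding (pad right/bottom): shape preserved
    n, h, wd, c = x.shape
    xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 0)), constant_values=-np.inf)
    windows = np.stack(
        [xp[:, dy : dy + h, dx : dx + wd, :] for dy, dx in _POOL_OFFSETS], axis=0
    )
    am = windows.argmax(axis=0)
    out = np.take_along_axis(windows, am[None], axis=0)[0]
    return out, am


def _maxpool_backward(dout, am, shape):
    n, h, wd, c = shape
    dxp = np.zeros((n, h + 1, wd + 1, c))
    for idx, (dy, dx) in enumerate(_POOL_OFFSETS):
        dxp[:, dy : dy + h, dx : dx + wd, :] += dout * (am == idx)
    return dxp[:, :h, :wd, :]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class CNNModel:
    """A NetworkSpec realized as NumPy weights with forward/backward passes."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.seed = seed
        self.history: list[float] = []
        self._rng = np.random.default_rng(seed)
        self.params: list[dict] = []
        shape = tuple(spec.input_shape)
        for lay in spec.layers:
            if lay.kind == "conv":
                kh, kw = lay.kernel
                fan_in = kh * kw * shape[2]
                w = self._rng.standard_normal((kh, kw, shape[2], lay.filters)) * np.sqrt(2.0 / fan_in)
                self.params.append({"w": w, "b": np.zeros(lay.filters)})
                shape = (shape[0], shape[1], lay.filters)
            elif lay.kind == "dense":
                fan_in = shape[0]
                scale = np.sqrt(2.0 / fan_in) if lay.activation == "relu" else np.sqrt(1.0 / fan_in)
                w = self._rng.standard_normal((fan_in, lay.filters)) * scale
                self.params.append({"w": w, "b": np.zeros(lay.filters)})
                shape = (lay.filters,)
            else:
                self.params.append({})
                if lay.kind == "flatten":
                    shape = (int(np.prod(shape)),)
        self._adam_state: Optional[list] = None

    # -- forward ------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False):
        """Return (softmax probabilities, cache for backprop)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match spec {self.spec.input_shape}"
            )
        cache = []
        out = x
        for lay, par in zip(self.spec.layers, self.params):
            if lay.kind == "conv":
                out, xp = _conv_forward(out, par["w"], par["b"])
                pre = out
                if lay.activation == "relu":
                    out = np.maximum(out, 0.0)
                cache.append(("conv", xp, pre))
            elif lay.kind == "maxpool":
                shape_in = out.shape
                out, am = _maxpool_forward(out)
                cache.append(("maxpool", am, shape_in))
            elif lay.kind == "dropout":
                if train and lay.rate > 0:
                    mask = (self._rng.random(out.shape) >= lay.rate) / (1.0 - lay.rate)
                    out = out * mask
                    cache.append(("dropout", mask))
                else:
                    cache.append(("dropout", None))
            elif lay.kind == "flatten":
                cache.append(("flatten", out.shape))
                out = out.reshape(out.shape[0], -1)
            elif lay.kind == "dense":
                inp = out
                z = out @ par["w"] + par["b"]
                if lay.activation == "relu":
                    out = np.maximum(z, 0.0)
                elif lay.activation == "softmax":
                    out = _softmax(z)
                else:
                    out = z
                cache.append(("dense", inp, z))
        return out, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Row-stochastic class probabilities."""
        probs, _ = self.forward(x, train=False)
        return probs

    def classify(self, x: np.ndarray) -> np.ndarray:
        return self.predict(x).argmax(axis=1)

    def penultimate(self, x: np.ndarray) -> np.ndarray:
        """Activations feeding the final dense head (inference mode)."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        out = x
        for lay, par in zip(self.spec.layers[:-1], self.params[:-1]):
            if lay.kind == "conv":
                out, _ = _conv_forward(out, par["w"], par["b"])
                if lay.activation == "relu":
                    out = np.maximum(out, 0.0)
            elif lay.kind == "maxpool":
                out, _ = _maxpool_forward(out)
            elif lay.kind == "flatten":
                out = out.reshape(out.shape[0], -1)
            elif lay.kind == "dense":
                z = out @ par["w"] + par["b"]
                out = np.maximum(z, 0.0) if lay.activation == "relu" else z
        return out

    # -- loss & backward ----------------------------------------------

    @staticmethod
    def mse_loss(probs: np.ndarray, targets: np.ndarray) -> float:
        return float(np.mean((probs - targets) ** 2))

    def _backward(self, probs, targets, cache):
        n, k = probs.shape
        g = 2.0 * (probs - targets) / (n * k)  # dL/dprobs
        # softmax jacobian-vector product
        grad = probs * (g - np.sum(g * probs, axis=1, keepdims=True))
        grads: list[dict] = [{} for _ in self.spec.layers]
        for idx in range(len(self.spec.layers) - 1, -1, -1):
            lay = self.spec.layers[idx]
            entry = cache[idx]
            if lay.kind == "dense":
                _, inp, z = entry
                if lay.activation == "relu":
                    grad = grad * (z > 0)
                # softmax handled above for the head; 'none' passes through
                grads[idx] = {"w": inp.T @ grad, "b": grad.sum(axis=0)}
                grad = grad @ self.params[idx]["w"].T
            elif lay.kind == "flatten":
                grad = grad.reshape(entry[1])
            elif lay.kind == "dropout":
                if entry[1] is not None:
                    grad = grad * entry[1]
            elif lay.kind == "maxpool":
                _, am, shape_in = entry
                grad = _maxpool_backward(grad, am, shape_in)
            elif lay.kind == "conv":
                _, xp, pre = entry
                if lay.activation == "relu":
                    grad = grad * (pre > 0)
                grad, dw, db = _conv_backward(grad, xp, self.params[idx]["w"])
                grads[idx] = {"w": dw, "b": db}
        return grads

    def _adam_step(self, grads, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_state is None:
            self._adam_state = [
                {k: np.zeros_like(v) for k, v in par.items()} for par in self.params
            ]
            self._adam_v = [
                {k: np.zeros_like(v) for k, v in par.items()} for par in self.params
            ]
        for par, g, m, v in zip(self.params, grads, self._adam_state, self._adam_v):
            for key in par:
                if key not in g:
                    continue
                m[key] = beta1 * m[key] + (1 - beta1) * g[key]
                v[key] = beta2 * v[key] + (1 - beta2) * g[key] ** 2
                mhat = m[key] / (1 - beta1**t)
                vhat = v[key] / (1 - beta2**t)
                par[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- final head helpers -------------------------------------------

    def get_head(self) -> np.ndarray:
        """Flattened weights+biases of the final dense layer."""
        par = self.params[-1]
        return np.concatenate([par["w"].ravel(), par["b"].ravel()])

    def set_head(self, flat: np.ndarray) -> None:
        par = self.params[-1]
        nw = par["w"].size
        flat = np.asarray(flat, dtype=float)
        if flat.size != nw + par["b"].size:
            raise ValueError("head vector length mismatch")
        par["w"] = flat[:nw].reshape(par["w"].shape)
        par["b"] = flat[nw:].copy()

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for i, par in enumerate(self.params):
            for k, v in par.items():
                arrays[f"layer{i}_{k}"] = v
        np.savez(path, **arrays)

    def load(self, path) -> None:
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        for i, par in enumerate(self.params):
            for k in par:
                par[k] = data[f"layer{i}_{k}"]


def build(spec: NetworkSpec, seed: int = 0) -> CNNModel:
    """Randomly initialized model; same seed gives identical weights."""
    return CNNModel(spec, seed=seed)


def reshape_features(v: FeatureVector | np.ndarray) -> np.ndarray:
    """Zero-pad a feature vector to 242 entries and reshape to 22x11x1."""
    vals = v.values if isinstance(v, FeatureVector) else np.asarray(v, dtype=float).ravel()
    if vals.size > PLANE_SIZE:
        raise ValueError(f"feature vector of length {vals.size} exceeds {PLANE_SIZE}")
    padded = np.zeros(PLANE_SIZE)
    padded[: vals.size] = vals
    return padded.reshape(*INPUT_SHAPE)


def train(
    model: CNNModel,
    x: np.ndarray,
    y: np.ndarray,
    epochs: Optional[int] = None,
    batch_size: Optional[int] = None,
    learning_rate: Optional[float] = None,
    seed: int = 0,
) -> CNNModel:
    """Adam / MSE training; ``epochs=0`` is a no-op. History appended in place."""
    epochs = model.spec.epochs if epochs is None else epochs
    batch_size = model.spec.batch_size if batch_size is None else batch_size
    lr = model.spec.learning_rate if learning_rate is None else learning_rate
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("targets must be one-hot with 2 columns")
    if len(np.unique(y.argmax(axis=1))) < 2:
        warnings.warn("training set contains a single class", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    t = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            probs, cache = model.forward(x[idx], train=True)
            losses.append(model.mse_loss(probs, y[idx]))
            grads = model._backward(probs, y[idx], cache)
            t += 1
            model._adam_step(grads, lr, t)
        model.history.append(float(np.mean(losses)))
    return model


def ffo_tune(
    model: CNNModel,
    x_tune: np.ndarray,
    y_tune: np.ndarray,
    ffo_config: Optional[_ffo.FFOConfig] = None,
    half_width: float = 1.0,
) -> CNNModel:
    """Tune the final dense head with the falcon finch optimizer.

    The head's weights+biases (130 numbers for the canonical spec) form the
    decision vector; fitness is the MSE of the softmax output on the tuning
    fold. The activations feeding the head are precomputed once, so each
    fitness evaluation is a single small matrix product. The search box is
    the current head ± ``half_width``, and the current head seeds the
    initial population, so the tuned fitness can never exceed the input
    model's. ``iter_max=0`` returns the model unchanged.
    """
    w0 = model.get_head()
    s = w0.size
    if ffo_config is None:
        ffo_config = _ffo.FFOConfig(l=20, s=s, iter_max=30, seed=0)
    if ffo_config.s != s:
        logger.info("ffo_tune: correcting config dimension %d -> %d", ffo_config.s, s)
        ffo_config.s = s
    if ffo_config.iter_max == 0:
        return model
    ffo_config.lower = w0 - half_width
    ffo_config.upper = w0 + half_width

    z = model.penultimate(x_tune)  # (n, 64)
    y = np.asarray(y_tune, dtype=float)
    n_w = model.params[-1]["w"].size
    w_shape = model.params[-1]["w"].shape

    def head_mse(flat: np.ndarray) -> float:
        logits = z @ flat[:n_w].reshape(w_shape) + flat[n_w:]
        return CNNModel.mse_loss(_softmax(logits), y)

    result = _ffo.optimize(head_mse, ffo_config, initial_guess=w0)
    if result.best_fitness <= head_mse(w0):
        model.set_head(result.best_position)
    return model
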