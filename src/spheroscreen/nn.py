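"""Compact numpy CNN engine used by the screening classifier.

Implements exactly the layer family the architecture module declares —
valid-padding convolution, ReLU, 2x2 max-pooling, flatten, dense, inverted
dropout and a softmax/cross-entropy head — with analytic backpropagation and
an Adam optimizer. Arrays are NHWC float32; all randomness (weight
initialization, dropout masks) derives from a single integer seed through
`numpy.random.SeedSequence`, so training is bit-reproducible on one machine.

The engine is deliberately small: stride-1 3x3 (or any odd/even kernel)
convolutions via `sliding_window_view` + `tensordot`, pool stride equal to
pool size with floor division on odd extents. Gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import ModelSpec, count_parameters, infer_shapes

__all__ = ["Network", "network_from_spec"]

_DT = np.float32


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(_Layer):
    """Valid-padding stride-1 convolution, NHWC, bias per output channel."""

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        fan_in = kh * kw * c_in
        fan_out = kh * kw * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(kh, kw, c_in, c_out)).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        kh, kw = self.W.shape[:2]
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (N, oh, ow, C, kh, kw)
        out = np.tensordot(win, self.W, axes=([3, 4, 5], [2, 0, 1]))
        out += self.b
        return np.ascontiguousarray(out, dtype=_DT)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        kh, kw = self.W.shape[:2]
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))
        dW = np.tensordot(win, dout, axes=([0, 1, 2], [0, 1, 2]))  # (C, kh, kw, F)
        self.grads[0][...] = dW.transpose(1, 2, 0, 3)
        self.grads[1][...] = dout.sum(axis=(0, 1, 2))
        # dx = full correlation of dout with spatially flipped kernels
        pad = ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1), (0, 0))
        dpad = np.pad(dout, pad)
        wrot = self.W[::-1, ::-1]  # (kh, kw, C_in, C_out)
        dwin = sliding_window_view(dpad, (kh, kw), axis=(1, 2))  # (N, H, W, F, kh, kw)
        dx = np.tensordot(dwin, wrot, axes=([3, 4, 5], [3, 0, 1]))
        return np.ascontiguousarray(dx, dtype=_DT)


class ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, _DT(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, _DT(0.0))


class MaxPool2x2(_Layer):
    """2x2 max-pool, stride 2; odd trailing rows/columns are dropped (floor)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xe = x[:, : h2 * 2, : w2 * 2]
        r = xe.reshape(n, h2, 2, w2, 2, c)
        out = r.max(axis=(2, 4))
        self._r = r
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._r == self._out[:, :, None, :, None, :]
        cnt = mask.sum(axis=(2, 4), keepdims=True)
        dr = mask * (dout[:, :, None, :, None, :] / cnt)
        dx = np.zeros(self._in_shape, dtype=_DT)
        dx[:, : h2 * 2, : w2 * 2] = dr.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Flatten(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(_Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(_DT) / _DT(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)


class Network:
    """A feed-forward stack with a softmax/cross-entropy head.

    `forward` returns class probabilities; `train_batch` performs one
    forward/backward pass and an Adam update, returning (loss, accuracy).
    """

    def __init__(self, layers: list[_Layer], n_classes: int, learning_rate: float = 1e-3):
        self.layers = layers
        self.n_classes = n_classes
        params, grads = [], []
        for lay in layers:
            params.extend(lay.params)
            grads.extend(lay.grads)
        self._params = params
        self._grads = grads
        self.optimizer = _Adam(params, lr=learning_rate)

    @property
    def n_parameters(self) -> int:
        """Total trainable parameters across all layers."""
        return int(sum(p.size for p in self._params))

    def _logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.asarray(x, dtype=_DT)
        if out.ndim == 3:
            out = out[..., None]
        for lay in self.layers:
            out = lay.forward(out, train)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return _softmax(self._logits(x, train))

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        chunks = [
            self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
        ]
        if not chunks:
            return np.zeros((0, self.n_classes), dtype=_DT)
        return np.concatenate(chunks, axis=0)

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """One optimization step. ``y`` holds integer class indices."""
        probs = _softmax(self._logits(x, train=True))
        n = len(x)
        eps = 1e-9
        loss = -float(np.mean(np.log(probs[np.arange(n), y] + eps)))
        acc = float(np.mean(probs.argmax(axis=1) == y))
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        grad /= _DT(n)
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        self.optimizer.step(self._params, self._grads)
        return loss, acc

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self._params, weights):
            p[...] = w


def network_from_spec(
    spec: ModelSpec,
    dropout_rate: float | None = None,
    seed: int = 0,
    learning_rate: float = 1e-3,
) -> Network:
    """Materialize a `Network` from a declarative `ModelSpec`.

    The instantiated parameter total always equals
    ``architecture.count_parameters(spec)[1]``.
    """
    shapes = infer_shapes(spec)  # validates the spec
    ss = np.random.SeedSequence(seed)
    layers: list[_Layer] = []
    shape: tuple[int, ...] = tuple(spec.input_shape)
    for lay_spec, (_, out_shape) in zip(spec.layers, shapes):
        if lay_spec.kind == "conv2d":
            rng = np.random.default_rng(ss.spawn(1)[0])
            kh, kw = lay_spec.kernel
            layers.append(Conv2D(kh, kw, shape[-1], lay_spec.filters, rng))
        elif lay_spec.kind == "activation_relu":
            layers.append(ReLU())
        elif lay_spec.kind == "maxpool2d":
            layers.append(MaxPool2x2())
        elif lay_spec.kind == "flatten":
            layers.append(Flatten())
        elif lay_spec.kind == "dense":
            rng = np.random.default_rng(ss.spawn(1)[0])
            layers.append(Dense(shape[0], lay_spec.filters, rng))
        elif lay_spec.kind == "dropout":
            rate = lay_spec.dropout_rate if dropout_rate is None else dropout_rate
            layers.append(Dropout(rate, np.random.default_rng(ss.spawn(1)[0])))
        elif lay_spec.kind == "activation_softmax":
            pass  # the Network head applies softmax
        shape = out_shape
    net = Network(layers, n_classes=spec.n_classes, learning_rate=learning_rate)
    expected = count_parameters(spec)[1]
    assert net.n_parameters == expected, (net.n_parameters, expected)
    return net
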