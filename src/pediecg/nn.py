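"""Minimal CPU neural-network layers with explicit backpropagation.

Float32 NHWC tensors throughout; convolutions run as im2col matrix
multiplications. Each layer caches what its backward pass needs and
accumulates parameter gradients in ``layer.grads`` mirroring
``layer.params``. This is deliberately small: the beat classifiers are
trained at desk scale on a single CPU, and the layer set covers exactly
what the two model families need (2-D and depthwise-separable
convolutions with optional stride, pooling, dense, dropout, residual
blocks).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def layers(self):
        yield self


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _pad_same(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    # x: (N, H, W, C) padded → windows (N, Ho, Wo, k, k, C)
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (N, Ho, Wo, C, k, k)
    win = win[:, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))


class Conv2D(Layer):
    """k×k 'same' convolution, optional stride, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.params = {
            "W": _he_init(rng, (k * k * c_in, c_out), k * k * c_in),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        xp = _pad_same(x, self.k)
        self._cols = _im2col(xp, self.k, self.stride)  # (N,Ho,Wo,k,k,C)
        n, ho, wo = self._cols.shape[:3]
        flat = self._cols.reshape(n * ho * wo, -1)
        out = flat @ self.params["W"] + self.params["b"]
        return out.reshape(n, ho, wo, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, ho, wo, _ = grad.shape
        gflat = grad.reshape(n * ho * wo, self.c_out)
        cols = self._cols.reshape(n * ho * wo, -1)
        self.grads["W"][...] = cols.T @ gflat
        self.grads["b"][...] = gflat.sum(axis=0)
        # dX: scatter gradient columns back into the padded input
        dcols = (gflat @ self.params["W"].T).reshape(
            n, ho, wo, self.k, self.k, self.c_in
        )
        _, h, w, _ = self._xshape
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s] += dcols[:, :, :, i, j]
        return dxp[:, p : p + h, p : p + w] if p else dxp


class DepthwiseConv2D(Layer):
    """k×k per-channel 'same' convolution (depthwise half of a
    separable convolution), optional stride."""

    def __init__(self, c: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.c = k, stride, c
        self.params = {
            "W": _he_init(rng, (k, k, c), k * k),
            "b": np.zeros(c, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        xp = _pad_same(x, self.k)
        self._win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))[
            :, :: self.stride, :: self.stride
        ]  # (N,Ho,Wo,C,k,k)
        out = np.einsum("nhwcij,ijc->nhwc", self._win, self.params["W"],
                        optimize=True) + self.params["b"]
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = np.einsum(
            "nhwcij,nhwc->ijc", self._win, grad, optimize=True
        )
        self.grads["b"][...] = grad.sum(axis=(0, 1, 2))
        n, ho, wo, c = grad.shape
        _, h, w, _ = self._xshape
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + ho * s : s, j : j + wo * s : s] += (
                    grad * self.params["W"][i, j]
                )
        return dxp[:, p : p + h, p : p + w] if p else dxp


class SeparableConv2D(Layer):
    """Depthwise k×k followed by pointwise 1×1 (Xception's building block)."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depthwise = DepthwiseConv2D(c_in, k, stride, rng)
        self.pointwise = Conv2D(c_in, c_out, k=1, stride=1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.pointwise.forward(self.depthwise.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(grad))

    def layers(self):
        yield self.depthwise
        yield self.pointwise


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2×2 max pooling, stride 2 (odd trailing row/column dropped)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._xshape = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c)
        out = xt.max(axis=(2, 4))
        self._mask = xt == out[:, :, None, :, None, :]
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        h2, w2 = h // 2, w // 2
        g = self._mask * grad[:, :, None, :, None, :]
        # ties share the gradient equally
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = g / counts
        dx = np.zeros((n, h, w, c), dtype=np.float32)
        dx[:, : h2 * 2, : w2 * 2] = g.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        return np.broadcast_to(
            grad[:, None, None, :] / (h * w), self._xshape
        ).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": _he_init(rng, (n_in, n_out), n_in),
            "b": np.zeros(n_out, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return (grad @ self.params["W"].T).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Residual(Layer):
    """out = body(x) + shortcut(x); shortcut is identity or a 1×1
    (possibly strided) projection when shapes differ."""

    def __init__(self, body: list[Layer], shortcut: Layer | None = None) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x
        for layer in self.body:
            out = layer.forward(out)
        short = self.shortcut.forward(x) if self.shortcut is not None else x
        return out + short

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for layer in reversed(self.body):
            g = layer.backward(g)
        gs = self.shortcut.backward(grad) if self.shortcut is not None else grad
        return g + gs

    def layers(self):
        for layer in self.body:
            yield from layer.layers()
        if self.shortcut is not None:
            yield from self.shortcut.layers()


class Sequential:
    """A stack of layers with a shared training flag."""

    def __init__(self, layers: list[Layer]) -> None:
        self._layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.all_layers():
            layer.training = training
        out = x
        for layer in self._layers:
            out = layer.forward(out)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self._layers):
            grad = layer.backward(grad)

    def all_layers(self):
        for layer in self._layers:
            yield from layer.layers()

    def parameters(self) -> list[tuple[Layer, str]]:
        return [
            (layer, name)
            for layer in self.all_layers()
            for name in layer.params
        ]

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"{i}:{name}": layer.params[name]
            for i, (layer, name) in enumerate(self.parameters())
        }

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, (layer, name) in enumerate(self.parameters()):
            layer.params[name] = state[f"{i}:{name}"].astype(np.float32).copy()
            layer.grads[name] = np.zeros_like(layer.params[name])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, model: Sequential, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in model.parameters()]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            layer.params[name] -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )
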