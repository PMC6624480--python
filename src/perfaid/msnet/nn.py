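"""Minimal 3D convolutional network engine (numpy, explicit backprop).

Implements exactly the pieces the multi-stream architecture needs: 3D
convolution (3x3x3, stride 1, same padding) via im2col + BLAS matmul,
ceil-mode 3D max pooling with per-dimension kernels, fully connected
layers, ReLU, and a softmax/cross-entropy head trained with mini-batch
SGD with momentum.  Everything runs in float32 and is deterministic given
the initialization seed and the batch order.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3D", "MaxPool3D", "ReLU", "Flatten", "Dense", "Sequential",
           "softmax", "SGDMomentum"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, same padding, over (N, C, d1, d2, d3)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 fan_in: int | None = None):
        """``fan_in`` overrides the He-init fan-in; on volumes smaller than
        the kernel most taps fall into the zero padding, so the effective
        fan-in is the number of taps that actually see data."""
        self.kernel = kernel
        k = int(np.prod(kernel)) * in_ch
        scale = np.sqrt(2.0 / (fan_in if fan_in is not None else k))
        self.w = (rng.standard_normal((out_ch, k)) * scale).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d1, d2, d3 = x.shape
        k1, k2, k3 = self.kernel
        p1, p2, p3 = k1 // 2, k2 // 2, k3 // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p1, p1), (p2, p2), (p3, p3)))
        win = sliding_window_view(xp, (k1, k2, k3), axis=(2, 3, 4))
        # (n, c, d1, d2, d3, k1, k2, k3) -> (n, P, c*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(n, d1 * d2 * d3, c * k1 * k2 * k3)
        out = cols @ self.w.T + self.b
        if train:
            self._cols = cols
            self._shape = (n, c, d1, d2, d3)
        return np.ascontiguousarray(
            out.transpose(0, 2, 1).reshape(n, self.out_ch, d1, d2, d3)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d1, d2, d3 = self._shape
        k1, k2, k3 = self.kernel
        p1, p2, p3 = k1 // 2, k2 // 2, k3 // 2
        p = d1 * d2 * d3
        g = grad.reshape(n, self.out_ch, p).transpose(0, 2, 1)  # (n, P, F)
        gf = g.reshape(-1, self.out_ch)
        self.dw = (gf.T @ self._cols.reshape(-1, self._cols.shape[2])).astype(np.float32)
        self.db = gf.sum(axis=0).astype(np.float32)
        dcols = (g @ self.w).reshape(n, d1, d2, d3, c, k1, k2, k3)
        dxp = np.zeros((n, c, d1 + 2 * p1, d2 + 2 * p2, d3 + 2 * p3), dtype=np.float32)
        for i in range(k1):
            for j in range(k2):
                for k in range(k3):
                    dxp[:, :, i:i + d1, j:j + d2, k:k + d3] += np.ascontiguousarray(
                        dcols[:, :, :, :, :, i, j, k].transpose(0, 4, 1, 2, 3)
                    )
        del self._cols
        return dxp[:, :, p1:p1 + d1, p2:p2 + d2, p3:p3 + d3]

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class MaxPool3D(Layer):
    """Ceil-mode max pooling; kernel equals stride per dimension."""

    def __init__(self, kernel: tuple[int, int, int]):
        self.kernel = tuple(int(k) for k in kernel)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d1, d2, d3 = x.shape
        k1, k2, k3 = self.kernel
        o1, o2, o3 = -(-d1 // k1), -(-d2 // k2), -(-d3 // k3)
        pad = (o1 * k1 - d1, o2 * k2 - d2, o3 * k3 - d3)
        xp = np.pad(
            x, ((0, 0), (0, 0), (0, pad[0]), (0, pad[1]), (0, pad[2])),
            constant_values=-np.inf,
        )
        win = xp.reshape(n, c, o1, k1, o2, k2, o3, k3)
        win = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 6, 3, 5, 7))
        flat = win.reshape(n, c, o1, o2, o3, k1 * k2 * k3)
        idx = np.argmax(flat, axis=5)
        out = np.take_along_axis(flat, idx[..., None], axis=5)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = (n, c, d1, d2, d3)
            self._out_dims = (o1, o2, o3)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, d1, d2, d3 = self._in_shape
        k1, k2, k3 = self.kernel
        o1, o2, o3 = self._out_dims
        flat = np.zeros((n, c, o1, o2, o3, k1 * k2 * k3), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=5)
        win = flat.reshape(n, c, o1, o2, o3, k1, k2, k3)
        win = win.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dxp = win.reshape(n, c, o1 * k1, o2 * k2, o3 * k3)
        return dxp[:, :, :d1, :d2, :d3]

    @property
    def n_params(self) -> int:
        return 0


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask

    @property
    def n_params(self) -> int:
        return 0


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)

    @property
    def n_params(self) -> int:
        return 0


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.w = (rng.standard_normal((out_features, in_features)) * scale).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = (grad.T @ self._x).astype(np.float32)
        self.db = grad.sum(axis=0).astype(np.float32)
        return grad @ self.w

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size


class Sequential:
    """Layer stack with a softmax/cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x  # logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x.astype(np.float32), train=False))

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Cross-entropy loss on a batch, with gradients left in the layers."""
        logits = self.forward(x.astype(np.float32), train=True)
        probs = softmax(logits)
        n = len(y)
        loss = float(-np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean())
        grad = probs.astype(np.float32)
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p for p, _ in self.params_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params_grads()
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for (p, _), w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w


class SGDMomentum:
    """Classic momentum SGD: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, model: Sequential, lr: float, momentum: float):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in model.params_grads()]

    def step(self) -> None:
        for v, (p, g) in zip(self.velocity, self.model.params_grads()):
            v *= self.momentum
            v -= self.lr * g
            p += v
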