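"""Minimal 1-D convolutional network engine in NumPy.

Implements exactly the layer vocabulary the pain-classification FCN
needs — valid-mode 1-D convolution (stride 1), batch normalisation,
ReLU/Tanh/sigmoid activations, non-overlapping average pooling, flatten,
and a linear classifier — with explicit backpropagation and an Adam
optimiser.  Activations are carried in channel-last layout ``(B, L, C)``
so each convolution tap is a single large GEMM; the public network API
still speaks the conventional ``(B, C, S)`` ordering.

Everything is deterministic given the initialisation RNG and the data
order; there is no hidden global state.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def _bn_forward_train(x2, gamma, beta, eps):
    """Fused batch-norm training forward on (N, C) data: one accumulation
    pass for the batch moments, one pass producing xhat and the output."""
    N, C = x2.shape
    s = np.zeros(C)
    ss = np.zeros(C)
    for n in range(N):
        for c in range(C):
            v = float(x2[n, c])
            s[c] += v
            ss[c] += v * v
    mean = s / N
    var = ss / N - mean * mean
    for c in range(C):  # guard the analytic formula against cancellation
        if var[c] < 0.0:
            var[c] = 0.0
    inv = 1.0 / np.sqrt(var + eps)
    xhat = np.empty_like(x2)
    out = np.empty_like(x2)
    for n in range(N):
        for c in range(C):
            h = (float(x2[n, c]) - mean[c]) * inv[c]
            xhat[n, c] = h
            out[n, c] = gamma[c] * h + beta[c]
    return out, xhat, inv, mean, var


@numba.njit(cache=True, fastmath=True)
def _bn_backward_train(dout2, xhat2, inv, gamma):
    """Fused batch-norm training backward; returns (dx, dbeta, dgamma)."""
    N, C = dout2.shape
    sg = np.zeros(C)
    sgx = np.zeros(C)
    for n in range(N):
        for c in range(C):
            d = float(dout2[n, c])
            sg[c] += d
            sgx[c] += d * float(xhat2[n, c])
    a = gamma * inv
    b1 = sg / N
    b2 = sgx / N
    dx = np.empty_like(dout2)
    for n in range(N):
        for c in range(C):
            dx[n, c] = a[c] * (float(dout2[n, c]) - b1[c] - float(xhat2[n, c]) * b2[c])
    return dx, sg, sgx


class Layer:
    """Base class: forward caches what backward needs; params/grads are
    parallel dicts so the optimiser can walk them generically."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Valid-mode stride-1 convolution; weight layout (kernel, Cin, Cout).

    Initialisation is the seeded uniform fan-in scheme
    U(−1/√(Cin·K), +1/√(Cin·K)) for both weights and biases.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if kernel < 1 or in_channels < 1 or out_channels < 1:
            raise ValueError("kernel and channel counts must be >= 1")
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        bound = 1.0 / np.sqrt(in_channels * kernel)
        self.params["W"] = rng.uniform(-bound, bound, size=(kernel, in_channels, out_channels)).astype(dtype)
        self.params["b"] = rng.uniform(-bound, bound, size=out_channels).astype(dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, _ = x.shape
        L_out = L - self.kernel + 1
        if L_out < 1:
            raise ValueError(f"input length {L} shorter than kernel {self.kernel}")
        W, b = self.params["W"], self.params["b"]
        # cache the contiguous tap slices; backward reuses them for dW
        self._taps = [np.ascontiguousarray(x[:, j : j + L_out, :]).reshape(-1, self.in_channels) for j in range(self.kernel)]
        self._in_shape = x.shape
        out = np.empty((B * L_out, self.out_channels), dtype=x.dtype)
        np.matmul(self._taps[0], W[0], out=out)
        for j in range(1, self.kernel):
            out += self._taps[j] @ W[j]
        out += b
        return out.reshape(B, L_out, self.out_channels)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, _ = self._in_shape
        L_out = dout.shape[1]
        W = self.params["W"]
        dW = np.empty_like(W)
        dflat = np.ascontiguousarray(dout).reshape(-1, self.out_channels)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        for j in range(self.kernel):
            dW[j] = self._taps[j].T @ dflat
            dx[:, j : j + L_out, :] += (dflat @ W[j].T).reshape(B, L_out, self.in_channels)
        self.grads["W"] = dW
        self.grads["b"] = dflat.sum(axis=0)
        self._taps = None
        return dx


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over the (batch, length) axes.

    Inference statistics (``momentum=None``, the default) are a cumulative
    average of the batch moments seen since the last ``reset_epoch_stats``
    call; the training loop resets them at every epoch start so that
    validation always uses moments matching the current weights rather
    than a stale average over the whole optimisation history.  Pass a
    float momentum for the conventional exponential variant.
    """

    def __init__(self, channels: int, momentum: float | None = None, eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.n_batches = 0
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        self._train = train
        if train:
            out2, xhat2, inv, mean, var = _bn_forward_train(
                np.ascontiguousarray(x).reshape(-1, C),
                self.params["gamma"].astype(np.float64),
                self.params["beta"].astype(np.float64),
                self.eps,
            )
            self.n_batches += 1
            m = 1.0 / self.n_batches if self.momentum is None else self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
            self._xhat2, self._inv = xhat2, inv
            return out2.reshape(B, L, C)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        mean = self.running_mean.astype(x.dtype)
        xhat = x - mean
        xhat *= inv
        self._xhat2, self._inv = xhat.reshape(-1, C), inv
        out = xhat * self.params["gamma"]
        out += self.params["beta"]
        return out

    def reset_epoch_stats(self) -> None:
        """Restart the cumulative inference-statistics average (no-op for
        the exponential variant)."""
        if self.momentum is None:
            self.n_batches = 0

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = dout.shape
        dout2 = np.ascontiguousarray(dout).reshape(-1, C)
        if self._train:
            dx2, dbeta, dgamma = _bn_backward_train(
                dout2, self._xhat2, np.asarray(self._inv, dtype=np.float64),
                self.params["gamma"].astype(np.float64),
            )
            self.grads["gamma"] = dgamma.astype(self.params["gamma"].dtype)
            self.grads["beta"] = dbeta.astype(self.params["beta"].dtype)
            return dx2.reshape(B, L, C)
        self.grads["gamma"] = (dout2 * self._xhat2).sum(axis=0)
        self.grads["beta"] = dout2.sum(axis=0)
        return dout * (self.params["gamma"] * np.asarray(self._inv, dtype=dout.dtype))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.multiply(x, self._mask, out=x)  # in place: upstream caches survive

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.multiply(dout, self._mask, out=dout)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._y = np.tanh(x, out=x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout *= 1.0 - self._y**2
        return dout


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class AvgPool1d(Layer):
    """Non-overlapping average pooling (stride = kernel, floor division);
    trailing samples that do not fill a pool are dropped."""

    def __init__(self, kernel: int) -> None:
        super().__init__()
        if kernel < 1:
            raise ValueError("pool kernel must be >= 1")
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        L_out = L // self.kernel
        self._in_shape = x.shape
        return x[:, : L_out * self.kernel, :].reshape(B, L_out, self.kernel, C).mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        L_out = dout.shape[1]
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : L_out * self.kernel, :] = np.repeat(dout / self.kernel, self.kernel, axis=1)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.params["W"] = rng.uniform(-bound, bound, size=(in_features, out_features)).astype(dtype)
        self.params["b"] = rng.uniform(-bound, bound, size=out_features).astype(dtype)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def state(self) -> list[np.ndarray]:
        """Copies of all learnable parameters and batch-norm running stats."""
        out = []
        for layer in self.layers:
            for name in sorted(layer.params):
                out.append(layer.params[name].copy())
            if isinstance(layer, BatchNorm1d):
                out.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.layers:
            for name in sorted(layer.params):
                layer.params[name] = next(it).copy()
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, model: Sequential, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.model.parameters()):
            key = (i, name)
            g = layer.grads[name].astype(np.float64)
            if key not in self.m:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            update = self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)
            layer.params[name] = (layer.params[name].astype(np.float64) - update).astype(layer.params[name].dtype)
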