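"""Minimal numpy neural-network core for the hashing encoder.

Implements exactly the layers the encoder architecture needs — embedding
lookup, 1-D convolution with "same" padding, ReLU, batch normalization,
average pooling, global average pooling — each with an explicit backward
pass, plus an Adam optimizer. Layers are stateless with respect to
activations: ``forward`` returns ``(output, cache)`` and ``backward``
consumes the cache, so a single trunk can be run on several batches per
step (the Siamese ontic/query passes) without aliasing issues.

Array layout convention: batches of sequences are ``(B, C, L)`` —
batch, channels, length.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5


class Layer:
    """Base: trainable parameters live in ``self.params`` (name -> array)."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, object]:
        raise NotImplementedError

    def backward(
        self, cache: object, grad_out: np.ndarray, grads: dict[str, np.ndarray]
    ) -> np.ndarray:
        """Return grad wrt input; accumulate parameter grads into ``grads``."""
        raise NotImplementedError


class Embedding(Layer):
    """Token-id lookup: (B, L) int -> (B, dim, L) float."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, 0.1, size=(vocab_size, dim))

    def forward(self, tokens: np.ndarray, train: bool):
        out = self.params["W"][tokens]              # (B, L, dim)
        return np.ascontiguousarray(out.transpose(0, 2, 1)), tokens

    def backward(self, cache, grad_out, grads):
        tokens = cache
        gW = grads.setdefault("W", np.zeros_like(self.params["W"]))
        g = grad_out.transpose(0, 2, 1).reshape(-1, grad_out.shape[1])  # (B*L, dim)
        np.add.at(gW, tokens.ravel(), g)
        return None  # nothing upstream of the embedding


class Conv1d(Layer):
    """1-D convolution, "same" zero padding, stride 1, He-initialized."""

    def __init__(
        self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        self.kernel = kernel
        fan_in = in_ch * kernel
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel))
        self.params["b"] = np.zeros(out_ch)

    def forward(self, x: np.ndarray, train: bool):
        B, C, L = x.shape
        k = self.kernel
        p = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        # (B, C, L, k) windows -> (B*L, C*k) patch matrix
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        patches = win.transpose(0, 2, 1, 3).reshape(B * L, C * k)
        Wmat = self.params["W"].reshape(self.params["W"].shape[0], C * k)
        out = patches @ Wmat.T + self.params["b"]
        out = out.reshape(B, L, -1).transpose(0, 2, 1)
        return np.ascontiguousarray(out), (patches, x.shape)

    def backward(self, cache, grad_out, grads):
        patches, (B, C, L) = cache
        k = self.kernel
        p = (k - 1) // 2
        out_ch = grad_out.shape[1]
        g = grad_out.transpose(0, 2, 1).reshape(B * L, out_ch)
        Wmat = self.params["W"].reshape(out_ch, C * k)
        grads["W"] = grads.get("W", 0) + (g.T @ patches).reshape(self.params["W"].shape)
        grads["b"] = grads.get("b", 0) + g.sum(axis=0)
        gpatch = (g @ Wmat).reshape(B, L, C, k).transpose(0, 2, 1, 3)  # (B, C, L, k)
        gxp = np.zeros((B, C, L + 2 * p))
        for j in range(k):
            gxp[:, :, j : j + L] += gpatch[:, :, :, j]
        return gxp[:, :, p : p + L]


class ReLU(Layer):
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        return out, x > 0
    def backward(self, cache, grad_out, grads):
        return grad_out * cache


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and length.

    Training uses batch statistics and updates exponential running
    averages; inference uses the running averages, so encoding is
    deterministic once training stops.
    """

    def __init__(self, channels: int, momentum: float = 0.9) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        out = self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]
        return out, (xhat, inv_std, train)

    def backward(self, cache, grad_out, grads):
        xhat, inv_std, was_train = cache
        grads["gamma"] = grads.get("gamma", 0) + (grad_out * xhat).sum(axis=(0, 2))
        grads["beta"] = grads.get("beta", 0) + grad_out.sum(axis=(0, 2))
        g_xhat = grad_out * self.params["gamma"][None, :, None]
        if not was_train:
            return g_xhat * inv_std[None, :, None]
        m = grad_out.shape[0] * grad_out.shape[2]
        mean_g = g_xhat.mean(axis=(0, 2))
        mean_gx = (g_xhat * xhat).mean(axis=(0, 2))
        return inv_std[None, :, None] * (
            g_xhat - mean_g[None, :, None] - xhat * mean_gx[None, :, None]
        )


class AvgPool1d(Layer):
    """Non-overlapping average pooling; trailing remainder is dropped."""

    def __init__(self, window: int = 2) -> None:
        super().__init__()
        self.window = window

    def forward(self, x, train):
        B, C, L = x.shape
        w = self.window
        Lo = L // w
        out = x[:, :, : Lo * w].reshape(B, C, Lo, w).mean(axis=3)
        return out, (x.shape, Lo)

    def backward(self, cache, grad_out, grads):
        (B, C, L), Lo = cache
        w = self.window
        gx = np.zeros((B, C, L))
        gx[:, :, : Lo * w] = np.repeat(grad_out / w, w, axis=2)
        return gx


class GlobalAvgPool(Layer):
    """(B, C, L) -> (B, C) mean over the length axis."""

    def forward(self, x, train):
        return x.mean(axis=2), x.shape

    def backward(self, cache, grad_out, grads):
        B, C, L = cache
        return np.broadcast_to(grad_out[:, :, None] / L, (B, C, L)).copy()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam over a named parameter dict (shared storage with the layers)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            g = grads.get(name)
            if g is None:
                continue
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1 ** self.t)
            vhat = self.v[name] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
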