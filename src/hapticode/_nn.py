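"""Minimal 1-D convolutional network engine (numpy, CPU).

Implements exactly the pieces the vibrotactile autoencoder needs: same-padding
1-D convolutions, max pooling, step-repetition upsampling, ReLU/sigmoid
activations, mean-absolute-error loss and Adam.

Arrays are float32 in channels-first (channels, batch, length) layout: with
the channel axis leading, each convolution reduces to one large GEMM over
the flattened batch-by-length axis with no transposes, which is what makes
CPU training viable. All randomness comes from an explicit numpy Generator,
so training is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "MaxPool1D",
    "UpSample1D",
    "Sequential",
    "Adam",
    "mae_loss",
]

_F32 = np.float32


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # clip to keep exp in range; float32 saturates around |x| ~ 88
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Conv1D:
    """Same-padding 1-D convolution with a fused activation.

    ReLU layers use He-normal weights with a small positive bias; the
    sigmoid output layer uses Glorot-uniform weights with zero bias.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        activation: str,
        rng: np.random.Generator,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.activation = activation
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        if activation == "relu":
            # He-normal init and a small positive bias: ReLU stacks with
            # Glorot/zero-bias init die too often at these widths
            self.W = (rng.standard_normal((out_channels, in_channels, kernel_size))
                      * np.sqrt(2.0 / fan_in)).astype(_F32)
            self.b = np.full(out_channels, 0.01, dtype=_F32)
        else:
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W = rng.uniform(-limit, limit,
                                 size=(out_channels, in_channels, kernel_size)).astype(_F32)
            self.b = np.zeros(out_channels, dtype=_F32)
        self._xp: np.ndarray | None = None
        self._out: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input layout is channels-first without a batch GEMM: (C, B, L)."""
        C, B, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        K = self.kernel_size
        pad = K // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        Lp = L + 2 * pad
        # all taps in one GEMM: (K*O, C) @ (C, B*Lp), then shifted adds
        Wstack = np.ascontiguousarray(self.W.transpose(2, 0, 1)).reshape(K * self.out_channels, C)
        G = (Wstack @ xp.reshape(C, B * Lp)).reshape(K, self.out_channels, B, Lp)
        z = np.empty((self.out_channels, B, L), dtype=_F32)
        z[...] = self.b[:, None, None]
        for j in range(K):
            z += G[j][:, :, j : j + L]
        if self.activation == "relu":
            out = _relu(z)
        elif self.activation == "sigmoid":
            out = _sigmoid(z)
        else:
            out = z
        if training:
            self._xp = xp
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = self._out
        if self.activation == "relu":
            grad = grad * (out > 0)
        elif self.activation == "sigmoid":
            grad = grad * out * (1.0 - out)
        xp = self._xp
        O, B, L = grad.shape
        C = self.in_channels
        K = self.kernel_size
        pad = K // 2
        g2 = grad.reshape(O, B * L)
        self.db[...] = g2.sum(axis=1)
        # weight gradient: one GEMM against the K shifted input copies
        Xsh = np.empty((K, C, B * L), dtype=_F32)
        for j in range(K):
            Xsh[j] = xp[:, :, j : j + L].reshape(C, B * L)
        dWflat = g2 @ Xsh.reshape(K * C, B * L).T  # (O, K*C)
        self.dW[...] = dWflat.reshape(O, K, C).transpose(0, 2, 1)
        # input gradient: one GEMM, then shifted scatter-adds
        Wd = np.ascontiguousarray(self.W.transpose(2, 1, 0)).reshape(K * C, O)
        D = (Wd @ g2).reshape(K, C, B, L)
        dxp = np.zeros_like(xp)
        for j in range(K):
            dxp[:, :, j : j + L] += D[j]
        self._xp = self._out = None
        return dxp[:, :, pad : pad + L]


class MaxPool1D:
    """Non-overlapping max pooling (window == stride)."""

    def __init__(self, pool: int):
        self.pool = pool
        self._idx: np.ndarray | None = None
        self._in_len: int | None = None

    params: list = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if L % self.pool:
            raise ValueError(f"length {L} not divisible by pool {self.pool}")
        xr = x.reshape(B, C, L // self.pool, self.pool)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._in_len = L
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, Lo = grad.shape
        dxr = np.zeros((B, C, Lo, self.pool), dtype=_F32)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        self._idx = None
        return dxr.reshape(B, C, self._in_len)


class UpSample1D:
    """Upsampling by repeating each time step `factor` times."""

    def __init__(self, factor: int):
        self.factor = factor

    params: list = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.repeat(x, self.factor, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = grad.shape
        return grad.reshape(B, C, L // self.factor, self.factor).sum(axis=-1)


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def mae_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error over every element, and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(_F32)
    return loss, grad


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-7).

    ``lr_scales`` optionally assigns each parameter a multiplier on the
    base learning rate (used for width-compensated steps: a unit's drift
    per Adam step grows with its fan-in, so wide layers need smaller
    steps to stay out of saturation).
    """

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, lr_scales=None):
        self.params = params
        self.lr = lr
        self.lr_scales = [1.0] * len(params) if lr_scales is None else list(lr_scales)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for (p, g), m, v, scale in zip(self.params, self.m, self.v, self.lr_scales):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= (self.lr * scale) * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
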