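"""Compact numpy implementation of the spectral 1-D convolutional network.

Architecture (fixed topology, configurable widths):

    input (1 x L) -> Conv1 -> BatchNorm -> ReLU
                  -> Conv2 -> BatchNorm -> ReLU -> Dropout
                  -> FullyConnected -> scalar

Convolutions use stride 1 and same-padding; training minimizes the
half-mean-square error 0.5 * mean((pred - y)^2) with an Adam optimizer.
Batch normalization keeps running statistics for evaluation mode; dropout is
inverted (active only in training).  Everything is driven by a single
``numpy.random.Generator`` so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CNN1DNet"]


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L+k-1) padded input -> (B, C, k, L) sliding windows (view)."""
    B, C, Lp = xp.shape
    L = Lp - k + 1
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, k, L), strides=(s[0], s[1], s[2], s[2]),
        writeable=False,
    )


class _Conv1d:
    def __init__(self, rng, c_in, c_out, k):
        self.k = k
        self.W = _he(rng, (c_out, c_in, k), c_in * k)
        self.b = np.zeros(c_out)

    def forward(self, x):
        # x: (B, C_in, L); same padding
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = _im2col(xp, self.k)           # (B, C_in, k, L)
        self._cols = cols
        self._in_shape = x.shape
        return np.einsum("bckl,ock->bol", cols, self.W, optimize=True) \
            + self.b[None, :, None]

    def backward(self, gy):
        # gy: (B, C_out, L)
        self.gW = np.einsum("bol,bckl->ock", gy, self._cols, optimize=True)
        self.gb = gy.sum(axis=(0, 2))
        B, C, L = self._in_shape
        pad = self.k // 2
        gx_pad = np.zeros((B, C, L + 2 * pad))
        # scatter-add each kernel tap
        contrib = np.einsum("bol,ock->bckl", gy, self.W, optimize=True)
        for t in range(self.k):
            gx_pad[:, :, t:t + L] += contrib[:, :, t, :]
        return gx_pad[:, :, pad:pad + L]

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm1d:
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        # x: (B, C, L); normalize per channel over (B, L)
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, gy):
        xhat = self._xhat
        B, C, L = gy.shape
        m = B * L
        self.ggamma = (gy * xhat).sum(axis=(0, 2))
        self.gbeta = gy.sum(axis=(0, 2))
        gxhat = gy * self.gamma[None, :, None]
        gx = (gxhat - gxhat.mean(axis=(0, 2), keepdims=True)
              - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True) / m
              ) / self._std[None, :, None]
        return gx


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class _Dropout:
    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, train, rng):
        if train and self.rate > 0:
            self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, gy):
        return gy * self._mask if self._mask is not None else gy


class CNN1DNet:
    """The network with its optimizer state.  Operates on standardized
    inputs of shape (B, L); target is a standardized scalar per sample."""

    def __init__(self, input_length: int, channels=(16, 32), kernel_size=3,
                 dropout=0.2, seed: int = 0):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if input_length < 2 * (kernel_size // 2) * 2 + 1:
            raise ValueError(
                f"input length {input_length} is below the receptive field "
                f"of two kernel-{kernel_size} convolutions"
            )
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        self.conv1 = _Conv1d(rng, 1, c1, kernel_size)
        self.bn1 = _BatchNorm1d(c1)
        self.relu1 = _ReLU()
        self.conv2 = _Conv1d(rng, c1, c2, kernel_size)
        self.bn2 = _BatchNorm1d(c2)
        self.relu2 = _ReLU()
        self.drop = _Dropout(dropout)
        self.Wfc = _he(rng, (c2 * input_length,), c2 * input_length)
        self.bfc = 0.0
        self.L = input_length
        self._adam = {}
        self._t = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, train: bool, rng=None) -> np.ndarray:
        x = X[:, None, :]                     # (B, 1, L)
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x), train))
        h = self.relu2.forward(self.bn2.forward(self.conv2.forward(h), train))
        h = self.drop.forward(h, train, rng)
        self._flat = h.reshape(h.shape[0], -1)
        self._h_shape = h.shape
        return self._flat @ self.Wfc + self.bfc

    def backward(self, gy: np.ndarray) -> None:
        # gy: (B,) gradient of loss wrt network output
        self.gWfc = self._flat.T @ gy
        self.gbfc = gy.sum()
        gh = np.outer(gy, self.Wfc).reshape(self._h_shape)
        gh = self.drop.backward(gh)
        gh = self.bn2.backward(self.relu2.backward(gh))
        gh = self.conv2.backward(gh)
        gh = self.bn1.backward(self.relu1.backward(gh))
        self.conv1.backward(gh)

    # -- optimizer ----------------------------------------------------------

    def _param_grads(self):
        return [
            (self.conv1, "W", "gW"), (self.conv1, "b", "gb"),
            (self.bn1, "gamma", "ggamma"), (self.bn1, "beta", "gbeta"),
            (self.conv2, "W", "gW"), (self.conv2, "b", "gb"),
            (self.bn2, "gamma", "ggamma"), (self.bn2, "beta", "gbeta"),
            (self, "Wfc", "gWfc"), (self, "bfc", "gbfc"),
        ]

    def adam_step(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._t += 1
        t = self._t
        for i, (obj, pname, gname) in enumerate(self._param_grads()):
            g = getattr(obj, gname)
            m, v = self._adam.get(i, (0.0, 0.0))
            m = beta1 * m + (1 - beta1) * g
            v = beta2 * v + (1 - beta2) * np.square(g)
            self._adam[i] = (m, v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            setattr(obj, pname,
                    getattr(obj, pname) - lr * mhat / (np.sqrt(vhat) + eps))

    # -- checkpointing ------------------------------------------------------

    def state(self) -> dict:
        out = {}
        for i, (obj, pname, _) in enumerate(self._param_grads()):
            out[i] = np.copy(getattr(obj, pname))
        out["bn1_stats"] = (self.bn1.run_mean.copy(), self.bn1.run_var.copy())
        out["bn2_stats"] = (self.bn2.run_mean.copy(), self.bn2.run_var.copy())
        return out

    def load_state(self, state: dict) -> None:
        for i, (obj, pname, _) in enumerate(self._param_grads()):
            setattr(obj, pname, np.copy(state[i]))
        self.bn1.run_mean, self.bn1.run_var = (
            state["bn1_stats"][0].copy(), state["bn1_stats"][1].copy()
        )
        self.bn2.run_mean, self.bn2.run_var = (
            state["bn2_stats"][0].copy(), state["bn2_stats"][1].copy()
        )
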