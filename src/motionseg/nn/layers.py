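"""Layers with explicit forward/backward passes.

Tensor layout is channels-first: convolutional activations are
``(N, C, D, H, W)``; dense activations are ``(N, F)``.  Each layer owns its
parameter arrays in ``params`` and accumulates gradients of the *mean* batch
loss into ``grads`` during :meth:`backward`.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Default compute/parameter dtype.  Single precision is ample for training
#: these networks and roughly halves both memory traffic and BLAS time;
#: construct layers with ``dtype=np.float64`` where full precision is needed
#: (e.g. finite-difference gradient verification).
DEFAULT_DTYPE = np.float32


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError("expected a scalar or length-3 value")
    return t


class Layer:
    """Base layer: holds parameter/gradient arrays and an l1/l2 penalty."""

    def __init__(self, dtype=None) -> None:
        self.dtype = np.dtype(dtype if dtype is not None else DEFAULT_DTYPE)
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self.l1 = 0.0
        self.l2 = 0.0

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def regularization_loss(self) -> float:
        """L1L2 penalty on the weight array (params[0]); also adds its
        gradient contribution, so call once per optimization step."""
        if not self.params or (self.l1 == 0.0 and self.l2 == 0.0):
            return 0.0
        W = self.params[0]
        self.grads[0] += self.l1 * np.sign(W) + 2.0 * self.l2 * W
        return float(self.l1 * np.abs(W).sum() + self.l2 * (W ** 2).sum())

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s


class Conv3D(Layer):
    """3D convolution, SAME padding, optional stride (no pooling anywhere:
    all spatial reduction in the pipeline goes through strided convolutions).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size=3,
        stride=1,
        l1: float = 0.0,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=None,
    ) -> None:
        super().__init__(dtype)
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = in_channels, out_channels
        self.k = _triple(kernel_size)
        self.stride = _triple(stride)
        fan_in = in_channels * int(np.prod(self.k))
        scale = np.sqrt(2.0 / fan_in)
        W = rng.normal(0.0, scale, size=(out_channels, in_channels, *self.k))
        W = W.astype(self.dtype)
        b = np.zeros(out_channels, dtype=self.dtype)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]
        self.l1, self.l2 = l1, l2

    def _pads(self, shape):
        pads, outs = [], []
        for n, k, s in zip(shape, self.k, self.stride):
            out = -(-n // s)  # ceil
            total = max((out - 1) * s + k - n, 0)
            pads.append((total // 2, total - total // 2))
            outs.append(out)
        return pads, outs

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        N, C = x.shape[:2]
        pads, outs = self._pads(x.shape[2:])
        xp = np.pad(x, [(0, 0), (0, 0)] + pads)
        kd, kh, kw = self.k
        sd, sh, sw = self.stride
        win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        P = int(np.prod(outs))
        cols = cols.reshape(N, P, C * kd * kh * kw)
        Wm = self.params[0].reshape(self.cout, -1)
        out = cols @ Wm.T + self.params[1]
        self._cache = (cols, xp.shape, pads, outs, x.shape)
        return out.transpose(0, 2, 1).reshape(N, self.cout, *outs)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, pads, outs, x_shape = self._cache
        N = dout.shape[0]
        dout = np.asarray(dout, dtype=self.dtype)
        P, K = cols.shape[1:]
        dres = np.ascontiguousarray(
            dout.reshape(N, self.cout, P).transpose(0, 2, 1)
        ).reshape(N * P, self.cout)
        dW = dres.T @ cols.reshape(N * P, K)  # flat GEMM
        self.grads[0] += dW.reshape(self.params[0].shape)
        self.grads[1] += dres.sum(axis=0)
        dcols = dres @ self.params[0].reshape(self.cout, K)  # (N*P, cin*k^3)
        kd, kh, kw = self.k
        sd, sh, sw = self.stride
        Do, Ho, Wo = outs
        dcols = dcols.reshape(N, Do, Ho, Wo, self.cin, kd, kh, kw)
        # Scatter-add (col2im) in channels-last layout so each destination
        # slice is contiguous along the channel axis.
        dxp = np.zeros((N,) + tuple(xp_shape[2:]) + (self.cin,), dtype=self.dtype)
        for a in range(kd):
            for b in range(kh):
                for c in range(kw):
                    dxp[:, a : a + Do * sd : sd,
                        b : b + Ho * sh : sh,
                        c : c + Wo * sw : sw, :] += dcols[..., a, b, c]
        sl = tuple(
            slice(p[0], p[0] + n) for p, n in zip(pads, x_shape[2:])
        )
        return dxp[(slice(None),) + sl].transpose(0, 4, 1, 2, 3)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        l1: float = 0.0,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
        dtype=None,
    ) -> None:
        super().__init__(dtype)
        rng = rng or np.random.default_rng(0)
        W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        W = W.astype(self.dtype)
        b = np.zeros(out_features, dtype=self.dtype)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]
        self.l1, self.l2 = l1, l2

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = np.asarray(x, dtype=self.dtype)
        return self._x @ self.params[0] + self.params[1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.params[0].T


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Swish(Layer):
    """x * sigmoid(x)."""

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._sig = 1.0 / (1.0 + np.exp(-x))
        self._x = x
        return x * self._sig

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s = self._sig
        return dout * (s + self._x * s * (1.0 - s))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization for (N, C, D, H, W) tensors."""

    def __init__(
        self, channels: int, momentum: float = 0.9, eps: float = 1e-5, dtype=None
    ) -> None:
        super().__init__(dtype)
        self.eps = eps
        self.momentum = momentum
        gamma = np.ones(channels, dtype=self.dtype)
        beta = np.zeros(channels, dtype=self.dtype)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels, dtype=self.dtype)
        self.running_var = np.ones(channels, dtype=self.dtype)

    @staticmethod
    def _bc(v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        axes = (0, 2, 3, 4)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - self._bc(mu)) / self._bc(std)
        self._cache = (xhat, std, x.shape, training)
        return self._bc(self.params[0]) * xhat + self._bc(self.params[1])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, std, shape, training = self._cache
        axes = (0, 2, 3, 4)
        self.grads[0] += (dout * xhat).sum(axis=axes)
        self.grads[1] += dout.sum(axis=axes)
        dxhat = dout * self._bc(self.params[0])
        if not training:
            # running statistics are constants: no batch-stat terms
            return dxhat / self._bc(std)
        M = shape[0] * shape[2] * shape[3] * shape[4]
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * xhat).sum(axis=axes)
        return (dxhat - self._bc(s1) / M - xhat * self._bc(s2) / M) / self._bc(std)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params] + [
            self.running_mean.copy(), self.running_var.copy()
        ]

    def load_state(self, state: list[np.ndarray]) -> None:
        self.params[0][...] = state[0]
        self.params[1][...] = state[1]
        self.running_mean = state[2].copy()
        self.running_var = state[3].copy()


class Upsample3D(Layer):
    """Nearest-neighbour spatial upsampling by a factor of 2, optionally
    cropped to a target spatial shape (to realign with a skip connection)."""

    def __init__(self, target_shape: tuple[int, int, int] | None = None) -> None:
        super().__init__()
        self.target_shape = target_shape

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._in_spatial = x.shape[2:]
        y = x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
        self._up_spatial = y.shape[2:]
        if self.target_shape is not None:
            y = y[:, :, : self.target_shape[0], : self.target_shape[1], : self.target_shape[2]]
        self._out_spatial = y.shape[2:]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._out_spatial != self._up_spatial:
            pad = [(0, u - o) for u, o in zip(self._up_spatial, self._out_spatial)]
            dout = np.pad(dout, [(0, 0), (0, 0)] + pad)
        N, C = dout.shape[:2]
        D, H, W = self._in_spatial
        return dout.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))
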