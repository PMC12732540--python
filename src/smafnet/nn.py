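"""Minimal 1-D neural-network layers with analytic gradients.

Everything the classifier needs — valid/same 1-D convolution, max-pooling,
dense layers, ReLU/sigmoid, and squeeze-and-excitation channel attention — is
implemented directly on NumPy arrays.  Each layer caches what its backward
pass needs during ``forward`` and accumulates parameter gradients in-place;
``backward`` returns the gradient with respect to the layer input.  All
gradients are verified against central finite differences in the test suite.

Feature maps are ``(batch, channels, length)`` float64 arrays.  Convolutions
run through an im2col lowering so the inner loop is a single matmul.

Weight initialization is uniform fan-in scaling, U(-1/sqrt(fan_in),
+1/sqrt(fan_in)); biases start at zero.  Every layer draws from the RNG it is
handed, so a model built from one seeded generator is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "MaxPool1d",
    "Dense",
    "ReLU",
    "Sigmoid",
    "SqueezeExcite",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    """Base class: parameter/gradient bookkeeping shared by all layers."""

    def parameters(self) -> dict[str, np.ndarray]:
        return {}

    def gradients(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.gradients().values():
            g[...] = 0.0


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with ``valid`` or ``same`` padding.

    ``valid`` emits length n - k + 1 (no padding, stride 1); ``same`` pads
    (k - 1) // 2 zeros on each side and requires odd k, so parallel branches
    with different kernel sizes stay length-aligned.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        *,
        padding: str = "valid",
        bias: bool = True,
        rng: np.random.Generator,
    ) -> None:
        if kernel_size < 1:
            raise ValueError("kernel size must be >= 1")
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and kernel_size % 2 == 0:
            raise ValueError("same padding requires an odd kernel size")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        fan_in = in_channels * kernel_size
        self.W = _fan_in_uniform(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.b = np.zeros(out_channels) if bias else None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> dict[str, np.ndarray]:
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def gradients(self) -> dict[str, np.ndarray]:
        g = {"W": self.gW}
        if self.gb is not None:
            g["b"] = self.gb
        return g

    def forward(self, x: np.ndarray) -> np.ndarray:
        batch, c_in, t = x.shape
        if c_in != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c_in}")
        k = self.kernel_size
        pad = (k - 1) // 2 if self.padding == "same" else 0
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad))) if pad else x
        t_pad = xp.shape[2]
        if t_pad < k:
            raise ValueError(f"input length {t} too short for kernel {k}")
        t_out = t_pad - k + 1
        # im2col: (B, Cin, Tout, k) -> (B, Tout, Cin*k)
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        cols = np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(
            batch, t_out, c_in * k
        )
        w_mat = self.W.reshape(self.out_channels, c_in * k)
        y = cols @ w_mat.T  # (B, Tout, Cout)
        if self.b is not None:
            y += self.b
        self._cache = (cols, x.shape, pad)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, x_shape, pad = self._cache
        batch, c_in, t = x_shape
        k = self.kernel_size
        g = grad_out.transpose(0, 2, 1)  # (B, Tout, Cout)
        t_out = g.shape[1]
        w_mat = self.W.reshape(self.out_channels, c_in * k)
        self.gW += np.einsum("btc,btp->cp", g, cols).reshape(self.W.shape)
        if self.gb is not None:
            self.gb += g.sum(axis=(0, 1))
        g_cols = g @ w_mat  # (B, Tout, Cin*k)
        g_cols = g_cols.reshape(batch, t_out, c_in, k).transpose(0, 2, 3, 1)
        gx = np.zeros((batch, c_in, t + 2 * pad))
        for i in range(k):  # col2im scatter-add; k <= 16 so the loop is cheap
            gx[:, :, i : i + t_out] += g_cols[:, :, i, :]
        return gx[:, :, pad : pad + t] if pad else gx


class MaxPool1d(Layer):
    """Max-pooling; with the default size 2 / stride 2 the length floors-halves."""

    def __init__(self, size: int = 2, stride: int | None = None) -> None:
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size
        self.stride = stride if stride is not None else size
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        batch, c, t = x.shape
        if t < self.size:
            raise ValueError(f"length {t} shorter than pool size {self.size}")
        t_out = (t - self.size) // self.stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=2)
        windows = windows[:, :, :: self.stride][:, :, :t_out]  # (B, C, Tout, size)
        arg = windows.argmax(axis=3)
        y = np.take_along_axis(windows, arg[..., None], axis=3)[..., 0]
        self._cache = (arg, x.shape, t_out)
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        arg, x_shape, t_out = self._cache
        gx = np.zeros(x_shape)
        batch, c, _ = x_shape
        # absolute input position of each window's max
        pos = arg + self.stride * np.arange(t_out)[None, None, :]
        bi = np.arange(batch)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(gx, (bi, ci, pos), grad_out)
        return gx


class Dense(Layer):
    """Fully connected layer, ``y = x @ W.T + b`` with W shaped (out, in)."""

    def __init__(
        self, in_features: int, out_features: int, *, rng: np.random.Generator
    ) -> None:
        self.W = _fan_in_uniform(rng, (out_features, in_features), in_features)
        self.b = np.zeros(out_features)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def parameters(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def gradients(self) -> dict[str, np.ndarray]:
        return {"W": self.gW, "b": self.gb}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.gW += grad_out.T @ self._x
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = sigmoid(x)
        return self._y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._y * (1.0 - self._y)


class SqueezeExcite(Layer):
    """Squeeze-and-excitation channel attention for (B, C, T) feature maps.

    Squeeze: global average pool over the temporal axis -> one scalar per
    channel.  Excitation: bottleneck C -> C/r (ReLU) -> C (sigmoid) producing
    per-channel weights in (0, 1).  Reweight: channel-wise multiplication of
    the input by those weights.
    """

    def __init__(self, channels: int, reduction: int = 8, *, rng: np.random.Generator) -> None:
        if channels % reduction != 0:
            raise ValueError("channels must be divisible by the reduction ratio")
        self.channels = channels
        self.fc1 = Dense(channels, channels // reduction, rng=rng)
        self.relu = ReLU()
        self.fc2 = Dense(channels // reduction, channels, rng=rng)
        self.sig = Sigmoid()

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, sub in (("fc1", self.fc1), ("fc2", self.fc2)):
            for k, v in sub.parameters().items():
                out[f"{name}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for name, sub in (("fc1", self.fc1), ("fc2", self.fc2)):
            for k, v in sub.gradients().items():
                out[f"{name}.{k}"] = v
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        self._x = x
        z = x.mean(axis=2)  # squeeze: (B, C)
        s = self.sig.forward(self.fc2.forward(self.relu.forward(self.fc1.forward(z))))
        self._s = s
        return x * s[:, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x, s = self._x, self._s
        gx = grad_out * s[:, :, None]
        gs = (grad_out * x).sum(axis=2)  # (B, C)
        gz = self.fc1.backward(self.relu.backward(self.fc2.backward(self.sig.backward(gs))))
        gx += gz[:, :, None] / x.shape[2]
        return gx
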