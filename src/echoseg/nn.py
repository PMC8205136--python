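"""Small NumPy convolutional-network toolkit with explicit backpropagation.

Implements exactly the building blocks the expanded U-Net needs — same-padded
convolution, stride-2 transposed convolution, 2x2 max pooling, batch
normalization, leaky ReLU, inverted dropout, channel softmax/sigmoid heads and
an Adam optimizer — on CPU in float64, using the NCHW layout throughout.
Every layer caches what its backward pass needs during ``forward`` and writes
parameter gradients into ``self.grads`` during ``backward``; layers are used
once per pass, so gradients are assigned, not accumulated.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "MaxPool2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Dropout",
    "channel_softmax",
    "softmax_backward",
    "sigmoid",
    "sigmoid_backward",
    "Adam",
]


class Layer:
    """Base layer: trainable arrays in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold k x k patches of an NCHW tensor into (N, C*k*k, H*W) columns."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            cols[:, :, a, b] = x[:, :, a : a + h, b : b + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, shape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` — scatter-add columns back onto the image."""
    n, c, h, w = shape
    dpad = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, h, w)
    for a in range(k):
        for b in range(k):
            dpad[:, :, a : a + h, b : b + w] += dcols[:, :, a, b]
    if pad:
        return dpad[:, :, pad:-pad, pad:-pad]
    return dpad


class Conv2d(Layer):
    """k x k convolution, stride 1, "same" zero padding, He-initialised."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("same-padded convolution requires an odd kernel size")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.params["weight"] = rng.normal(0.0, scale,
                                           (out_channels, in_channels, kernel_size, kernel_size))
        self.params["bias"] = np.zeros(out_channels)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        k = self.kernel_size
        pad = k // 2
        cols = _im2col(x, k, pad)
        w2 = self.params["weight"].reshape(self.out_channels, -1)
        out = np.matmul(w2, cols) + self.params["bias"][:, None]
        self._cache = (x.shape, cols)
        return out.reshape(n, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n, _, h, w = x_shape
        k = self.kernel_size
        df = dout.reshape(n, self.out_channels, h * w)
        self.grads["bias"] = df.sum(axis=(0, 2))
        self.grads["weight"] = np.einsum("nol,nkl->ok", df, cols).reshape(
            self.params["weight"].shape)
        w2 = self.params["weight"].reshape(self.out_channels, -1)
        dcols = np.matmul(w2.T, df)
        return _col2im(dcols, x_shape, k, k // 2)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x up-sampling).

    Kernel and stride match, so output blocks never overlap and the operation
    is a per-pixel linear map onto disjoint 2x2 output tiles.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = 2
        scale = np.sqrt(2.0 / in_channels)
        self.params["weight"] = rng.normal(0.0, scale, (in_channels, out_channels, 2, 2))
        self.params["bias"] = np.zeros(out_channels)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        self._x = x
        t = np.tensordot(x, self.params["weight"], axes=([1], [0]))  # (n,h,w,o,2,2)
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_channels, 2 * h, 2 * w)
        return out + self.params["bias"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        d = dout.reshape(n, self.out_channels, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.grads["bias"] = dout.sum(axis=(0, 2, 3))
        self.grads["weight"] = np.tensordot(x, d, axes=([0, 2, 3], [0, 1, 2]))
        dx = np.tensordot(d, self.params["weight"], axes=([3, 4, 5], [1, 2, 3]))
        return dx.transpose(0, 3, 1, 2)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        xr = (x.reshape(n, c, h // 2, 2, w // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h // 2, w // 2, 4))
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), arg = self._cache
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(d4, arg[..., None], dout[..., None], axis=-1)
        return (d4.reshape(n, c, h // 2, w // 2, 2, 2)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(n, c, h, w))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, train)
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        if not train:
            return dxhat * invstd[None, :, None, None]
        n, _, h, w = dout.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01) -> None:
        super().__init__()
        self.negative_slope = negative_slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.negative_slope * dout)


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def channel_softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of an NCHW tensor."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. logits given probabilities ``p`` and upstream ``dp``."""
    return p * (dp - (p * dp).sum(axis=1, keepdims=True))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    return dp * p * (1.0 - p)


class Adam:
    """Adam optimizer over the parameters of a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                m = self._m.setdefault(key, np.zeros_like(p))
                v = self._v.setdefault(key, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
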