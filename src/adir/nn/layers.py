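"""3D convolutional building blocks with analytic backward passes.

All tensors are float32 and shaped (N, C, D, H, W).  Convolution loops over
kernel offsets, each contributing one channel-mixing GEMM against the padded
volume; forward, weight-gradient and input-gradient passes all share this
scheme, so the working set stays cache-resident instead of materializing an
im2col matrix k^3 times the volume size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "InstanceNorm3d",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "NearestUpsample3d",
    "Sequential",
]

_DT = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=_DT)
        self.grad = np.zeros_like(self.data)


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []


class Conv3d(Layer):
    """3D convolution (cross-correlation) with stride and zero padding.

    All three passes loop over the k^3 kernel offsets and run one
    channel-mixing GEMM per offset against the (cache-resident) padded
    volume, which avoids materializing the k^3-times-larger im2col matrix.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        init_gain: float = np.sqrt(2.0),
    ):
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = in_channels, out_channels, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        if self.pad > kernel - 1:
            raise ValueError("padding must not exceed kernel - 1")
        fan_in = in_channels * kernel**3
        w = rng.normal(0.0, init_gain / np.sqrt(fan_in), size=(out_channels, in_channels) + (kernel,) * 3)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self._xp: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _offsets(self):
        k = self.k
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    yield i, j, l

    def _window(self, i: int, j: int, l: int, do: int, ho: int, wo: int):
        s = self.stride
        return (
            slice(i, i + (do - 1) * s + 1, s),
            slice(j, j + (ho - 1) * s + 1, s),
            slice(l, l + (wo - 1) * s + 1, s),
        )

    def _out_extent(self, xp_shape) -> tuple[int, int, int]:
        return tuple((s - self.k) // self.stride + 1 for s in xp_shape[2:])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DT)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3) if p else x
        n = x.shape[0]
        do, ho, wo = self._out_extent(xp.shape)
        xf = xp.reshape(n, self.cin, -1)
        out = np.zeros((n, self.cout, do, ho, wo), dtype=_DT)
        buf = np.empty((n, self.cout, xf.shape[2]), dtype=_DT)
        for i, j, l in self._offsets():
            np.matmul(self.weight.data[:, :, i, j, l], xf, out=buf)
            out += buf.reshape(xp.shape[0], self.cout, *xp.shape[2:])[
                (slice(None), slice(None), *self._window(i, j, l, do, ho, wo))
            ]
        if self.bias is not None:
            out += self.bias.data[None, :, None, None, None]
        self._xp = xp if train else None
        self._xshape = x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        assert self._xp is not None, "forward(train=True) must precede backward"
        xp = self._xp
        gout = np.ascontiguousarray(gout, dtype=_DT)
        n, f, do, ho, wo = gout.shape
        g2 = gout.reshape(n, f, -1)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 2))

        pdim = do * ho * wo
        xbuf = np.empty((n, self.cin, do, ho, wo), dtype=_DT)
        xbuf2 = xbuf.reshape(n, self.cin, pdim)
        gpad = np.zeros_like(xp)
        zbuf = np.empty((n, self.cin, pdim), dtype=_DT)
        for i, j, l in self._offsets():
            win = (slice(None), slice(None), *self._window(i, j, l, do, ho, wo))
            # weight gradient: correlate gout with the input window
            xbuf[...] = xp[win]
            self.weight.grad[:, :, i, j, l] += np.matmul(
                g2, xbuf2.transpose(0, 2, 1)
            ).sum(axis=0)
            # input gradient: scatter W^T @ gout back into the padded grid
            np.matmul(self.weight.data[:, :, i, j, l].T, g2, out=zbuf)
            gpad[win] += zbuf.reshape(n, self.cin, do, ho, wo)
        p = self.pad
        if p:
            gpad = gpad[:, :, p:-p, p:-p, p:-p]
        return gpad


class InstanceNorm3d(Layer):
    """Per-sample, per-channel feature standardization with affine scale/shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=_DT)
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv) if train else None
        return self.gamma.data[None, :, None, None, None] * xhat + self.beta.data[None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = (2, 3, 4)
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += gout.sum(axis=(0, 2, 3, 4))
        gxhat = gout * self.gamma.data[None, :, None, None, None]
        m1 = gxhat.mean(axis=axes, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=axes, keepdims=True)
        return inv * (gxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        out = np.where(mask, x, self.slope * x).astype(_DT, copy=False)
        self._mask = mask if train else None
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, self.slope * gout)


class Tanh(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.tanh(x, dtype=_DT)
        self._y = y if train else None
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * (1.0 - self._y**2)


class Sigmoid(Layer):
    def __init__(self):
        self._y = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = (1.0 / (1.0 + np.exp(-x))).astype(_DT, copy=False)
        self._y = y if train else None
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._y * (1.0 - self._y)


class NearestUpsample3d(Layer):
    """Nearest-neighbour upsampling by an integer factor per spatial axis."""

    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        f = self.f
        return np.ascontiguousarray(
            x.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
        )

    def backward(self, gout: np.ndarray) -> np.ndarray:
        f = self.f
        n, c, d, h, w = gout.shape
        g = gout.reshape(n, c, d // f, f, h // f, f, w // f, f)
        return g.sum(axis=(3, 5, 7))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            gout = l.backward(gout)
        return gout
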