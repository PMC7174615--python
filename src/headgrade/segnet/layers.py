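"""Trainable layers with explicit forward/backward passes.

Tensors are NCHW float64.  Convolutions use im2col/col2im; the decoder's
transposed convolutions use kernel == stride (non-overlapping learned
upsampling), which keeps both passes cheap and exact.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import lrelu_softplus, lrelu_softplus_grad, relu_grad

__all__ = ["Param", "Conv2d", "BlockUpsample", "Dropout", "ResidualBlock",
           "ActLReLUSoftplus", "ActReLU"]


class Param:
    """A learnable array with its gradient and momentum buffer."""

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.velocity = np.zeros_like(value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2-D convolution, 'same' padding for odd kernels, optional stride."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3,
                 stride: int = 1):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.W = Param(he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.b = Param(np.zeros(out_ch))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        oh, ow = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
        wmat = self.W.value.reshape(self.out_ch, -1)
        y = cols @ wmat.T + self.b.value
        if train:
            self._cols, self._xshape, self._osize = cols, x.shape, (oh, ow)
        return y.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, s, p = self.kernel, self.stride, self.pad
        oh, ow = self._osize
        dymat = dy.transpose(0, 2, 3, 1).reshape(n, oh * ow, self.out_ch)
        self.W.grad += np.einsum("nio,nij->oj", dymat, self._cols,
                                 optimize=True).reshape(self.W.value.shape)
        self.b.grad += dymat.sum(axis=(0, 1))
        wmat = self.W.value.reshape(self.out_ch, -1)
        dcols = (dymat @ wmat).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for a in range(k):
            for b in range(k):
                dxp[:, :, a:a + oh * s:s, b:b + ow * s:s] += \
                    dcols[:, :, :, :, a, b].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class BlockUpsample(Layer):
    """Transposed convolution with kernel == stride.

    Maps an (N, C, h, w) grid to (N, O, h*s, w*s); each input pixel paints a
    learned s x s block, so the operation is an exact inverse-stride
    deconvolution with no overlap.  s = 1 reduces to a 1x1 convolution.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, scale: int):
        self.in_ch, self.out_ch, self.scale = in_ch, out_ch, scale
        self.W = Param(he_init(rng, (in_ch, out_ch, scale, scale), in_ch))
        self.b = Param(np.zeros(out_ch))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        s = self.scale
        t = np.tensordot(x, self.W.value, axes=([1], [0]))  # (n,h,w,O,s,s)
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_ch, h * s, w * s)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        s = self.scale
        dyt = dy.reshape(n, self.out_ch, h, s, w, s).transpose(0, 2, 4, 1, 3, 5)
        self.W.grad += np.einsum("nchw,nhwost->cost", self._x, dyt, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("nhwost,cost->nchw", dyt, self.W.value, optimize=True)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class BatchNorm2d(Layer):
    """Per-channel batch normalization with learned scale/shift.

    Training uses batch statistics over (N, H, W) and keeps exponential
    running averages for inference, as in the ResNet family.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        n = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
        return dx * inv[None, :, None, None]


class ActReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._x = x
        return np.maximum(0.0, x)

    def backward(self, dy):
        return dy * relu_grad(self._x)


class ActLReLUSoftplus(Layer):
    def __init__(self, a: float = 0.01):
        self.a = a

    def forward(self, x, train=True):
        if train:
            self._x = x
        return lrelu_softplus(x, self.a)

    def backward(self, dy):
        return dy * lrelu_softplus_grad(self._x, self.a)


class ResidualBlock(Layer):
    """y = ReLU(F(x) + Ws x) with F = conv3x3 -> BN -> ReLU -> conv3x3 -> BN.

    Batch normalization follows each convolution as in the ResNet family.
    The skip projection Ws is a strided 1x1 convolution (with BN) when the
    channel count or resolution changes, and the identity otherwise.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int = 1):
        self.conv1 = Conv2d(rng, in_ch, out_ch, kernel=3, stride=stride)
        self.bn1 = BatchNorm2d(out_ch)
        self.act1 = ActReLU()
        self.conv2 = Conv2d(rng, out_ch, out_ch, kernel=3, stride=1)
        self.bn2 = BatchNorm2d(out_ch)
        self.proj = None
        self.bn_proj = None
        if in_ch != out_ch or stride != 1:
            self.proj = Conv2d(rng, in_ch, out_ch, kernel=1, stride=stride)
            self.bn_proj = BatchNorm2d(out_ch)
        self.act_out = ActReLU()

    def params(self):
        ps = (self.conv1.params() + self.bn1.params()
              + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            ps += self.proj.params() + self.bn_proj.params()
        return ps

    def forward(self, x, train=True):
        f = self.act1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        f = self.bn2.forward(self.conv2.forward(f, train), train)
        if self.proj is None:
            skip = x
        else:
            skip = self.bn_proj.forward(self.proj.forward(x, train), train)
        return self.act_out.forward(f + skip, train)

    def backward(self, dy):
        dsum = self.act_out.backward(dy)
        df = self.bn2.backward(dsum)
        df = self.conv2.backward(df)
        df = self.conv1.backward(self.bn1.backward(self.act1.backward(df)))
        if self.proj is None:
            ds = dsum
        else:
            ds = self.proj.backward(self.bn_proj.backward(dsum))
        return df + ds
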