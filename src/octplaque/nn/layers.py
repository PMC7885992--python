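"""Minimal numpy layer framework with manual backpropagation.

Implements exactly the pieces the two networks need: 2-D/3-D
convolution (stride 1, 'same' zero padding), batch normalization, ReLU,
2×2 max pooling that records argmax indices, index-driven max unpooling,
flatten, linear, dropout.  Gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    __slots__ = ("value", "grad", "name", "trainable")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = True


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running stats)."""
        return []

    def set_buffers(self, arrays: list[np.ndarray]) -> None:
        pass

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _ConvND(Layer):
    """'Same' N-D convolution, stride 1, odd kernels; im2col + GEMM.

    The forward pass materializes the patch matrix once (contiguous),
    so both the output and the weight gradient are single BLAS calls;
    the input gradient scatters per kernel offset, which is a handful
    of strided slab additions instead of a full correlation.
    """

    def __init__(self, cin: int, cout: int, kernel, ndim: int, rng=None, name="conv"):
        kernel = (kernel,) * ndim if np.isscalar(kernel) else tuple(kernel)
        if len(kernel) != ndim or any(k % 2 == 0 for k in kernel):
            raise ValueError("kernel must have one odd size per spatial axis")
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.ndim = ndim
        self.cin, self.cout = cin, cout
        fan_in = cin * int(np.prod(kernel))
        self.W = Parameter(_he_init(rng, (cout, cin, *kernel), fan_in), f"{name}.W")
        self.b = Parameter(np.zeros(cout), f"{name}.b")
        #: set on the network's first layer: its input gradient is unused
        self.skip_input_grad = False

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        pads = [k // 2 for k in self.kernel]
        xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p) for p in pads])
        spatial = x.shape[2:]
        win = sliding_window_view(xp, self.kernel, axis=tuple(range(2, 2 + self.ndim)))
        # (N, C, *S, *K) -> (N, *S, C, *K) -> (N*prod(S), C*prod(K))
        win = np.moveaxis(win, 1, 1 + self.ndim)
        cols = np.ascontiguousarray(win).reshape(
            x.shape[0] * int(np.prod(spatial)), -1
        )
        self._cols = cols
        self._x_shape, self._xp_shape = x.shape, xp.shape
        wmat = self.W.value.reshape(self.cout, -1)
        out = cols @ wmat.T + self.b.value
        out = out.reshape(x.shape[0], *spatial, self.cout)
        return np.moveaxis(out, -1, 1)

    def backward(self, g):
        n = self._x_shape[0]
        spatial = self._x_shape[2:]
        gmat = np.ascontiguousarray(np.moveaxis(g, 1, -1)).reshape(-1, self.cout)
        self.W.grad += (gmat.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += gmat.sum(axis=0)
        if self.skip_input_grad:
            return None
        # dx = same-size convolution of g with the flipped, channel-swapped
        # kernel (stride-1 'same' conv with odd kernels is self-adjoint up
        # to this flip), so it is one more im2col + GEMM
        pads = [k // 2 for k in self.kernel]
        gp = np.pad(g, [(0, 0), (0, 0)] + [(p, p) for p in pads])
        gwin = sliding_window_view(gp, self.kernel, axis=tuple(range(2, 2 + self.ndim)))
        gwin = np.moveaxis(gwin, 1, 1 + self.ndim)
        gcols = np.ascontiguousarray(gwin).reshape(n * int(np.prod(spatial)), -1)
        flip = (slice(None), slice(None)) + (slice(None, None, -1),) * self.ndim
        wback = np.ascontiguousarray(
            np.swapaxes(self.W.value[flip], 0, 1)
        ).reshape(self.cin, -1)
        dx = (gcols @ wback.T).reshape(n, *spatial, self.cin)
        return np.moveaxis(dx, -1, 1)


class Conv2d(_ConvND):
    """3×3-style 'same' convolution, stride 1, odd kernels only."""

    def __init__(self, cin: int, cout: int, kernel=3, rng: np.random.Generator | None = None):
        super().__init__(cin, cout, kernel, ndim=2, rng=rng, name="conv")

    @property
    def kh(self):
        return self.kernel[0]

    @property
    def kw(self):
        return self.kernel[1]


class Conv3d(_ConvND):
    """'Same' 3-D convolution, stride (1,1,1), odd kernels only."""

    def __init__(self, cin: int, cout: int, kernel=(3, 5, 5), rng=None):
        super().__init__(cin, cout, kernel, ndim=3, rng=rng, name="conv3")


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def set_buffers(self, arrays):
        self.running_mean, self.running_var = [np.asarray(a, np.float32) for a in arrays]

    def _bshape(self, ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, training=False):
        axes = (0,) + tuple(range(2, x.ndim))
        self._axes = axes
        bs = self._bshape(x.ndim)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(bs)) * ivar.reshape(bs)
        self._xhat, self._ivar, self._training = xhat, ivar, training
        return self.gamma.value.reshape(bs) * xhat + self.beta.value.reshape(bs)

    def backward(self, g):
        axes, bs = self._axes, self._bshape(g.ndim)
        xhat, ivar = self._xhat, self._ivar
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        dxhat = g * self.gamma.value.reshape(bs)
        if not self._training:
            return dxhat * ivar.reshape(bs)
        m = g.size // g.shape[1]
        term = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m
        )
        return ivar.reshape(bs) * term


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class MaxPoolLast2(Layer):
    """2×2 stride-2 max pooling over the last two axes, recording indices.

    Works for any number of leading axes, so it serves both the 2-D
    segmenter (N, C, H, W) and the 3-D detector (N, C, D, H, W), where
    the pool size 2×2×1 never pools the pullback-depth axis.  Odd
    trailing rows/columns are dropped (floor pooling); unpooling
    restores the exact input shape with zeros there.
    """

    def forward(self, x, training=False):
        *lead, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[..., : Ho * 2, : Wo * 2]
        v = xc.reshape(*lead, Ho, 2, Wo, 2)
        v = np.moveaxis(v, -3, -2).reshape(*lead, Ho, Wo, 4)
        self.last_indices = v.argmax(axis=-1)
        self.last_input_shape = x.shape
        out = np.take_along_axis(v, self.last_indices[..., None], axis=-1)[..., 0]
        return out

    def backward(self, g):
        return _unpool_scatter(g, self.last_indices, self.last_input_shape)


def _unpool_scatter(x, indices, out_shape):
    *lead, H, W = out_shape
    Ho, Wo = H // 2, W // 2
    z = np.zeros((*x.shape, 4), dtype=x.dtype)
    np.put_along_axis(z, indices[..., None], x[..., None], axis=-1)
    z = z.reshape(*lead, Ho, Wo, 2, 2)
    z = np.moveaxis(z, -2, -3).reshape(*lead, Ho * 2, Wo * 2)
    if (H, W) != (Ho * 2, Wo * 2):
        pad = [(0, 0)] * len(lead) + [(0, H - Ho * 2), (0, W - Wo * 2)]
        z = np.pad(z, pad)
    return z


class MaxUnpoolLast2(Layer):
    """Max unpooling bound to a pooling layer's stored indices.

    Restores each pooled maximum to its original position and zeros
    elsewhere, reproducing the encoder's spatial layout in the decoder.
    """

    def __init__(self, pool: MaxPoolLast2):
        self.pool = pool

    def forward(self, x, training=False):
        self._indices = self.pool.last_indices
        self._out_shape = self.pool.last_input_shape
        return _unpool_scatter(x, self._indices, self._out_shape)

    def backward(self, g):
        *lead, H, W = self._out_shape
        Ho, Wo = H // 2, W // 2
        gc = g[..., : Ho * 2, : Wo * 2]
        v = gc.reshape(*lead, Ho, 2, Wo, 2)
        v = np.moveaxis(v, -3, -2).reshape(*lead, Ho, Wo, 4)
        return np.take_along_axis(v, self._indices[..., None], axis=-1)[..., 0]


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None, zero_init: bool = False):
        rng = rng or np.random.default_rng()
        if zero_init:
            w = np.zeros((n_out, n_in), dtype=np.float32)
        else:
            w = _he_init(rng, (n_out, n_in), n_in)
        self.W = Parameter(w, "linear.W")
        self.b = Parameter(np.zeros(n_out), "linear.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, g):
        self.W.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value


class Dropout(Layer):
    def __init__(self, rate: float, seed: int = 0):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(seed)

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    # -- state snapshot (parameters + buffers), used for early-stopping
    #    restore and checkpointing
    def all_layers(self) -> list[Layer]:
        return self.layers

    def get_state(self) -> list[np.ndarray]:
        out = []
        for layer in self.all_layers():
            out.extend(p.value.copy() for p in layer.params())
            out.extend(b.copy() for b in layer.buffers())
        return out

    def set_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.all_layers():
            for p in layer.params():
                p.value = np.asarray(next(it), dtype=np.float32).reshape(p.value.shape)
            nbuf = len(layer.buffers())
            if nbuf:
                layer.set_buffers([np.asarray(next(it)) for _ in range(nbuf)])

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
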