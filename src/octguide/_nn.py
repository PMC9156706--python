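"""Minimal CNN engine on numpy.

Implements exactly the pieces the guidance models need: 2-D convolution via
im2col, depthwise convolution, max/global-average pooling, dense layers,
residual / inception-style / separable-conv blocks, softmax cross-entropy and
MAPE losses, and SGD with Nesterov momentum and a hyperbolic learning-rate
decay schedule.

Layout is NHWC throughout; H is the depth (Z) axis of a B-scan, W the lateral
(X) axis.  All parameters are float32.  Every layer caches what its backward
pass needs on ``forward`` and releases it on ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "DepthwiseConv2D", "ReLU", "MaxPool2D",
    "Affine", "ParallelConcat", "BatchNorm", "BoxSmoothDepth", "BoxPool",
    "GlobalAvgPool", "GlobalAvgMaxPool", "MeanOverWidth",
    "AppendDepthCoord", "ContrastNorm",
    "CumMaxDepth", "Flatten", "Dense",
    "ResidualBlock", "InceptionBlock", "SeparableConvBlock",
    "Network", "SoftmaxCrossEntropy", "MAPELoss", "SGDNesterov",
]


class Layer:
    """Base class: a differentiable map with optional parameters."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list:
        """List of [value, gradient] pairs, updated in place by the optimizer."""
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _pad_same(x, kh, kw):
    ph, pw = kh // 2, kw // 2
    return np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0))), ph, pw


class Conv2D(Layer):
    """Valid or 'same' cross-correlation with stride, bias included."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding="valid", *, rng):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        sh, sw = (stride, stride) if np.isscalar(stride) else stride
        if padding == "same" and (sh != 1 or sw != 1):
            raise ValueError("'same' padding implemented for stride 1 only")
        self.kh, self.kw, self.sh, self.sw = kh, kw, sh, sw
        self.padding = padding
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = _he_init(rng, (in_ch * kh * kw, out_ch), in_ch * kh * kw)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.trainable = True
        #: first-layer convs may skip the input gradient (data below)
        self.needs_input_grad = True

    def _cols(self, x):
        # (N, Ho, Wo, C, kh, kw) view, strided
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        return win[:, :: self.sh, :: self.sw]

    def forward(self, x):
        if self.padding == "same":
            x, self._ph, self._pw = _pad_same(x, self.kh, self.kw)
        self._xshape = x.shape
        cols = self._cols(x)
        n, ho, wo = cols.shape[:3]
        self._cols_flat = np.ascontiguousarray(cols).reshape(n * ho * wo, -1)
        out = self._cols_flat @ self.W + self.b
        return out.reshape(n, ho, wo, self.out_ch)

    def backward(self, grad):
        n, ho, wo, _ = grad.shape
        g = grad.reshape(n * ho * wo, self.out_ch)
        self.dW[...] = self._cols_flat.T @ g
        self.db[...] = g.sum(axis=0)
        if not self.needs_input_grad:
            self._cols_flat = None
            return None
        dcols = (g @ self.W.T).reshape(n, ho, wo, self.in_ch, self.kh, self.kw)
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + self.sh * ho : self.sh,
                   j : j + self.sw * wo : self.sw] += dcols[:, :, :, :, i, j]
        self._cols_flat = None
        if self.padding == "same":
            dx = dx[:, self._ph : dx.shape[1] - self._ph or None,
                    self._pw : dx.shape[2] - self._pw or None]
        return dx

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]] if self.trainable \
            else []


class DepthwiseConv2D(Layer):
    """One filter per input channel (valid padding)."""

    def __init__(self, channels, kernel, stride=1, *, rng):
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        sh, sw = (stride, stride) if np.isscalar(stride) else stride
        self.kh, self.kw, self.sh, self.sw = kh, kw, sh, sw
        self.ch = channels
        self.W = _he_init(rng, (channels, kh, kw), kh * kw)
        self.b = np.zeros(channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._xshape = x.shape
        win = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        self._patches = win[:, :: self.sh, :: self.sw]  # (N,Ho,Wo,C,kh,kw)
        return np.einsum("nhwcij,cij->nhwc", self._patches, self.W,
                         optimize=True) + self.b

    def backward(self, grad):
        self.dW[...] = np.einsum("nhwcij,nhwc->cij", self._patches, grad,
                                 optimize=True)
        self.db[...] = grad.sum(axis=(0, 1, 2))
        dpatch = np.einsum("nhwc,cij->nhwcij", grad, self.W, optimize=True)
        n, ho, wo = grad.shape[:3]
        dx = np.zeros(self._xshape, dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + self.sh * ho : self.sh,
                   j : j + self.sw * wo : self.sw] += dpatch[:, :, :, :, i, j]
        self._patches = None
        return dx

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]


class BatchNorm(Layer):
    """Per-channel batch normalization with learnable scale and shift.

    Training mode normalizes by batch statistics and maintains running
    estimates (momentum 0.9) used in inference mode.
    """

    def __init__(self, channels, eps=1e-5, momentum=0.9):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mu
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
            self._ivstd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._ivstd
            self._m = x.size // x.shape[-1]
            return (self.gamma * self._xhat + self.beta).astype(np.float32)
        ivstd = 1.0 / np.sqrt(self.running_var + self.eps)
        self._eval_scale = self.gamma * ivstd
        return (self._eval_scale * (x - self.running_mean)
                + self.beta).astype(np.float32)

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        if not self.training:
            self.dgamma[...] = 0
            self.dbeta[...] = 0
            return grad * self._eval_scale
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        m = self._m
        dx = (self._ivstd / m) * (
            m * dxhat - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        self._xhat = None
        return dx.astype(np.float32)

    def params(self):
        return [[self.gamma, self.dgamma], [self.beta, self.dbeta]]

    def state_arrays(self):
        return [self.running_mean, self.running_var]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols that do not fill a
    window are dropped."""

    def __init__(self, size=2):
        self.p = size

    def forward(self, x):
        p = self.p
        n, h, w, c = x.shape
        ho, wo = h // p, w // p
        self._in_shape = x.shape
        r = x[:, : ho * p, : wo * p].reshape(n, ho, p, wo, p, c)
        r = r.transpose(0, 1, 3, 5, 2, 4).reshape(n, ho, wo, c, p * p)
        self._arg = r.argmax(axis=-1)
        return np.take_along_axis(r, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        p = self.p
        n, ho, wo, c = grad.shape
        flat = np.zeros((n, ho, wo, c, p * p), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        flat = flat.reshape(n, ho, wo, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, : ho * p, : wo * p] = flat.reshape(n, ho * p, wo * p, c)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               self._shape).astype(np.float32)


class GlobalAvgMaxPool(Layer):
    """Concatenated global average and global max pooling.

    The averaged half carries distributed texture/attenuation statistics;
    the max half turns spatially selective channels into existence
    detectors ('is there a dark shallow region anywhere').
    """

    def forward(self, x):
        n, h, w, c = x.shape
        self._shape = x.shape
        flat = x.reshape(n, h * w, c)
        self._arg = flat.argmax(axis=1)
        mx = np.take_along_axis(flat, self._arg[:, None, :], axis=1)[:, 0]
        return np.concatenate([flat.mean(axis=1), mx], axis=1)

    def backward(self, grad):
        n, h, w, c = self._shape
        g_avg, g_max = grad[:, :c], grad[:, c:]
        dflat = np.broadcast_to(g_avg[:, None, :] / (h * w),
                                (n, h * w, c)).astype(np.float32).copy()
        np.put_along_axis(
            dflat, self._arg[:, None, :],
            np.take_along_axis(dflat, self._arg[:, None, :], axis=1)
            + g_max[:, None, :], axis=1)
        return dflat.reshape(self._shape)


class MeanOverWidth(Layer):
    """Collapse the lateral (X) axis to its mean, keeping a 4-D tensor so
    that depth-wise (k, 1) convolutions can follow."""

    def forward(self, x):
        self._w = x.shape[2]
        return x.mean(axis=2, keepdims=True)

    def backward(self, grad):
        return np.broadcast_to(grad / self._w,
                               (grad.shape[0], grad.shape[1], self._w,
                                grad.shape[3])).astype(np.float32)


class AppendDepthCoord(Layer):
    """Append a normalized depth-coordinate channel (CoordConv-style).

    Lets position-blind conv channels become depth-aware — needed because a
    shallow stack's receptive field cannot otherwise tell 'dark near the
    needle tip' from 'dark at depth', and layer position along Z is exactly
    what distinguishes the epidural gap from attenuated deep tissue.
    """

    def forward(self, x):
        n, h, w, c = x.shape
        self._c = c
        z = np.linspace(-1.0, 1.0, h, dtype=np.float32)
        coord = np.broadcast_to(z[None, :, None, None], (n, h, w, 1))
        return np.concatenate([x, coord], axis=-1)

    def backward(self, grad):
        return grad[..., : self._c]


class ContrastNorm(Layer):
    """Per-sample, per-channel division by the spatial maximum.

    Makes downstream features invariant to overall backscatter amplitude,
    which in coherent imaging varies with coupling and subject; analogous to
    instance normalization without the centering term.
    """

    def __init__(self, eps=1e-6):
        self.eps = eps

    def forward(self, x):
        flat = x.reshape(x.shape[0], -1, x.shape[3])
        arg = flat.argmax(axis=1)                       # (N, C)
        m = np.take_along_axis(flat, arg[:, None, :], axis=1)
        self._x, self._arg, self._m = x, arg, m + self.eps
        return (flat / self._m).reshape(x.shape)

    def backward(self, grad):
        n, h, w, c = grad.shape
        gflat = grad.reshape(n, -1, c)
        xflat = self._x.reshape(n, -1, c)
        dx = gflat / self._m
        # max entries additionally receive -sum(g * x) / m^2
        corr = -(gflat * xflat).sum(axis=1, keepdims=True) / self._m ** 2
        np.put_along_axis(
            dx, self._arg[:, None, :],
            np.take_along_axis(dx, self._arg[:, None, :], axis=1) + corr,
            axis=1)
        self._x = None
        return dx.reshape(n, h, w, c)


class CumMaxDepth(Layer):
    """Causal cumulative max pooling along the depth (Z) axis.

    Output at depth z is the maximum over all shallower depths, producing a
    monotone envelope: a step at the first bright structure, insensitive to
    whatever lies deeper.  Gradient flows to the element that supplied each
    running maximum.
    """

    def forward(self, x):
        out = np.maximum.accumulate(x, axis=1)
        is_new = x >= out                               # x sets a new max
        z = np.arange(x.shape[1])[None, :, None, None]
        src = np.maximum.accumulate(np.where(is_new, z, -1), axis=1)
        self._src, self._shape = src, x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._shape
        dx = np.zeros(self._shape, dtype=np.float32)
        n_idx = np.arange(n)[:, None, None, None]
        w_idx = np.arange(w)[None, None, :, None]
        c_idx = np.arange(c)[None, None, None, :]
        np.add.at(dx, (n_idx, self._src, w_idx, c_idx), grad)
        self._src = None
        return dx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, *, rng):
        self.W = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        self._x = None
        return grad @ self.W.T

    def params(self):
        return [[self.W, self.dW], [self.b, self.db]]


class _Composite(Layer):
    """A layer built from sublayers; collects their parameters."""

    sublayers: list

    def params(self):
        out = []
        for s in self.sublayers:
            out.extend(s.params())
        return out


class ResidualBlock(_Composite):
    """conv-relu-conv plus identity (or strided 1x1 projection) shortcut,
    final ReLU — the basic skip-connection unit of residual networks."""

    def __init__(self, in_ch, out_ch, stride=1, kernel=(3, 3), *, rng):
        k = kernel
        self.conv1 = Conv2D(in_ch, out_ch, k, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(out_ch, out_ch, k, padding="same", rng=rng)
        # Valid conv1 shrinks the map; shortcut matches it with a strided
        # 3x3-window 1x1-equivalent projection (center tap of a 3x3 valid conv).
        self.proj = Conv2D(in_ch, out_ch, k, stride=stride, rng=rng)
        self.relu_out = ReLU()
        self.sublayers = [self.conv1, self.conv2, self.proj]

    def forward(self, x):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        short = self.proj.forward(x)
        return self.relu_out.forward(main + short)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        g_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        g_short = self.proj.backward(g)
        return g_main + g_short


class InceptionBlock(_Composite):
    """Parallel 1x1 / 3x3 / 5x5 'same' convolutions concatenated on the
    channel axis, each followed by ReLU."""

    def __init__(self, in_ch, ch1, ch3, ch5, kernel_axis="both", *, rng):
        if kernel_axis == "depth":          # 1-D branches along Z
            k1, k3, k5 = (1, 1), (3, 1), (5, 1)
        else:
            k1, k3, k5 = 1, 3, 5
        self.b1 = Conv2D(in_ch, ch1, k1, padding="same", rng=rng)
        self.b3 = Conv2D(in_ch, ch3, k3, padding="same", rng=rng)
        self.b5 = Conv2D(in_ch, ch5, k5, padding="same", rng=rng)
        self.r1, self.r3, self.r5 = ReLU(), ReLU(), ReLU()
        self.splits = (ch1, ch1 + ch3)
        self.sublayers = [self.b1, self.b3, self.b5]

    def forward(self, x):
        return np.concatenate(
            [self.r1.forward(self.b1.forward(x)),
             self.r3.forward(self.b3.forward(x)),
             self.r5.forward(self.b5.forward(x))], axis=-1)

    def backward(self, grad):
        g1, g3, g5 = np.split(grad, self.splits, axis=-1)
        return (self.b1.backward(self.r1.backward(g1))
                + self.b3.backward(self.r3.backward(g3))
                + self.b5.backward(self.r5.backward(g5)))


class BoxSmoothDepth(Layer):
    """Fixed box smoothing along the depth axis (zero-padded, odd width).

    Self-adjoint, so the backward pass applies the same filter to the
    gradient.
    """

    def __init__(self, size=9):
        if size % 2 != 1:
            raise ValueError("box size must be odd")
        self.size = size

    def _apply(self, x):
        from scipy.ndimage import uniform_filter1d
        return uniform_filter1d(x, self.size, axis=1, mode="constant",
                                cval=0.0)

    def forward(self, x):
        return self._apply(x)

    def backward(self, grad):
        return self._apply(grad)


class BoxPool(Layer):
    """Fixed strided box-average pooling (valid), channel-preserving."""

    def __init__(self, kernel, stride):
        self.kh, self.kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        self.sh, self.sw = (stride, stride) if np.isscalar(stride) else stride

    def forward(self, x):
        from scipy.ndimage import uniform_filter
        self._shape = x.shape
        n, h, w, c = x.shape
        ho = (h - self.kh) // self.sh + 1
        wo = (w - self.kw) // self.sw + 1
        # uniform_filter centers even windows half a sample left of center
        u = uniform_filter(x, size=(1, self.kh, self.kw, 1),
                           mode="constant", cval=0.0,
                           origin=(0, -(1 - self.kh % 2) and -1 or 0,
                                   -(1 - self.kw % 2) and -1 or 0, 0))
        oh, ow = (self.kh - 1) // 2, (self.kw - 1) // 2
        return np.ascontiguousarray(
            u[:, oh : oh + self.sh * ho : self.sh,
              ow : ow + self.sw * wo : self.sw])

    def backward(self, grad):
        n, ho, wo, c = grad.shape
        dx = np.zeros(self._shape, dtype=np.float32)
        g = grad / (self.kh * self.kw)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + self.sh * ho : self.sh,
                   j : j + self.sw * wo : self.sw] += g
        return dx


class Affine(Layer):
    """Fixed elementwise y = a x + b."""

    def __init__(self, a, b):
        self.a, self.b = np.float32(a), np.float32(b)

    def forward(self, x):
        return self.a * x + self.b

    def backward(self, grad):
        return self.a * grad


class ParallelConcat(_Composite):
    """Two stacks applied to the same input, concatenated on channels.

    Both stacks must produce spatially aligned maps.  Used to append fixed
    domain-informed feature maps (e.g. the epidural gap map) alongside the
    learned convolutional features.
    """

    def __init__(self, main_layers, side_layers):
        self.main = main_layers
        self.side = side_layers
        self.sublayers = list(main_layers) + list(side_layers)
        #: training loops may install precomputed side-branch maps here
        #: (the side stack is parameter-free, so its output per frame never
        #: changes during a run and its input gradient is not needed)
        self.side_override = None

    def _run(self, layers, x):
        for layer in layers:
            x = layer.forward(x)
        return x

    def run_side(self, x):
        return self._run(self.side, x)

    def forward(self, x):
        a = self._run(self.main, x)
        if self.side_override is not None:
            b = self.side_override
            self._side_computed = False
        else:
            b = self._run(self.side, x)
            self._side_computed = True
        if a.shape[:3] != b.shape[:3]:
            raise ValueError(
                f"parallel branches misaligned: {a.shape} vs {b.shape}")
        self._split = a.shape[3]
        return np.concatenate([a, b], axis=-1)

    def backward(self, grad):
        ga, gb = grad[..., : self._split], grad[..., self._split:]
        for layer in reversed(self.main):
            ga = layer.backward(ga)
            if ga is None:
                break
        if not self._side_computed:
            return ga
        for layer in reversed(self.side):
            gb = layer.backward(gb)
        return gb if ga is None else ga + gb


class SeparableConvBlock(_Composite):
    """Depthwise conv then pointwise 1x1 conv (the Xception building block),
    followed by ReLU."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, *, rng):
        self.dw = DepthwiseConv2D(in_ch, kernel, stride=stride, rng=rng)
        self.pw = Conv2D(in_ch, out_ch, 1, rng=rng)
        self.relu = ReLU()
        self.sublayers = [self.dw, self.pw]

    def forward(self, x):
        return self.relu.forward(self.pw.forward(self.dw.forward(x)))

    def backward(self, grad):
        return self.dw.backward(self.pw.backward(self.relu.backward(grad)))


class Network:
    """A plain sequential stack with helpers for training and Grad-CAM."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def _walk(self):
        stack = list(self.layers)
        while stack:
            layer = stack.pop(0)
            yield layer
            stack = list(getattr(layer, "sublayers", [])) + stack

    def set_training(self, flag: bool):
        for layer in self._walk():
            if hasattr(layer, "training"):
                layer.training = flag

    def _states(self):
        out = []
        for layer in self._walk():
            if hasattr(layer, "state_arrays"):
                out.extend(layer.state_arrays())
        return out

    def get_weights(self):
        return [p[0].copy() for p in self.params()] + \
            [s.copy() for s in self._states()]

    def set_weights(self, weights):
        params = self.params()
        for (p, _), w in zip(params, weights):
            p[...] = w
        for s, w in zip(self._states(), weights[len(params):]):
            s[...] = w

    def predict(self, x, batch_size=64):
        self.set_training(False)
        outs = [self.forward(x[i : i + batch_size])
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def forward_from(self, x, start):
        for layer in self.layers[start:]:
            x = layer.forward(x)
        return x

    def backward_to(self, grad, stop):
        """Backpropagate through layers[stop:], returning d(out)/d(input of
        layers[stop]) — i.e. the gradient w.r.t. the activation feeding
        layer ``stop``."""
        for layer in reversed(self.layers[stop:]):
            grad = layer.backward(grad)
        return grad


class SoftmaxCrossEntropy:
    """Sparse categorical cross-entropy on integer labels."""

    def loss_and_grad(self, logits, y):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        n = len(y)
        loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
        grad = p.copy()
        grad[np.arange(n), y] -= 1.0
        return float(loss), (grad / n).astype(np.float32)

    @staticmethod
    def probabilities(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class MAPELoss:
    """Mean absolute percentage error on a single-output regression head;
    ground truths must be strictly positive."""

    def loss_and_grad(self, pred, y):
        p = pred[:, 0]
        rel = (p - y) / y
        loss = 100.0 * np.abs(rel).mean()
        grad = (100.0 * np.sign(rel) / (y * len(y)))[:, None]
        return float(loss), grad.astype(np.float32)


class SGDNesterov:
    """SGD with Nesterov momentum and hyperbolic learning-rate decay.

    The effective rate at update t is lr / (1 + decay * t), with t counting
    individual batch updates (the legacy-Keras ``decay`` semantics); set
    ``decay_per='epoch'`` to count epochs instead.  The update is the
    Nesterov form  v <- m v - lr g ;  p <- p + m v - lr g.
    """

    def __init__(self, lr=0.01, momentum=0.9, decay=0.01, decay_per="step"):
        if decay_per not in ("step", "epoch"):
            raise ValueError("decay_per must be 'step' or 'epoch'")
        self.lr0 = lr
        self.momentum = momentum
        self.decay = decay
        self.decay_per = decay_per
        self._vel = {}
        self.epoch = 0
        self.iterations = 0

    @property
    def lr(self):
        t = self.iterations if self.decay_per == "step" else self.epoch
        return self.lr0 / (1.0 + self.decay * t)

    def step(self, params):
        m, lr = self.momentum, self.lr
        for i, (p, g) in enumerate(params):
            v = self._vel.get(i)
            if v is None:
                v = self._vel[i] = np.zeros_like(p)
            v *= m
            v -= lr * g
            p += m * v - lr * g
        self.iterations += 1
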