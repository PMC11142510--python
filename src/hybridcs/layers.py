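"""Neural-network layers used by the two-branch classifier.

Convolutions are lowered to gather + matmul on the autodiff tape (im2col):
an index table maps every output position to the flat input offsets of its
receptive field, a single fancy-index builds the patch matrix, and one BLAS
matmul applies all kernels at once.  The index tables are cached per input
shape.  A direct nested-loop implementation of the same operations lives in
:mod:`hybridcs.reference` and serves as the test oracle for this fast path.

Layout conventions: batches are leading, channels trailing —
2-D activations are ``(n, H, W, C)`` and 3-D activations ``(n, H, W, D, C)``
with ``D`` the spectral depth.
"""

from __future__ import annotations

import warnings

import numpy as np

from .autograd import Tensor, build_scatter, smish_core

__all__ = ["smish", "Conv2d", "Conv3d", "DepthwiseConv2d", "BatchNorm",
           "Linear", "AvgPool2d", "CBM", "SandglassBlock", "global_avg_pool"]


def smish(x):
    """Smish activation ``x * tanh(ln(1 + sigmoid(x)))``.

    A smooth, non-monotone-free, bounded-below nonlinearity; evaluated with
    log1p and a split-sign sigmoid so large |x| cannot overflow.  Accepts
    plain arrays/scalars or autodiff tensors.
    """
    if isinstance(x, Tensor):
        return smish_core(x)
    arr = np.asarray(x, dtype=float)
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    res = arr * np.tanh(np.log1p(out))
    return res if res.shape else float(res)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class _Layer:
    """Base: children register parameters as (name, Tensor) pairs."""

    def __init__(self, name: str):
        self.name = name
        self._params: list[tuple[str, Tensor]] = []

    def _add_param(self, pname: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self._params.append((f"{self.name}.{pname}", t))
        return t

    def named_params(self) -> list[tuple[str, Tensor]]:
        return list(self._params)


class Conv2d(_Layer):
    """Same-padded stride-1 2-D convolution over (n, H, W, Cin)."""

    def __init__(self, name, in_ch, out_ch, kernel, rng,
                 padding: str = "same"):
        super().__init__(name)
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.kh, self.kw = kh, kw
        self.in_ch, self.out_ch = in_ch, out_ch
        self.padding = padding
        fan_in = kh * kw * in_ch
        self.w = self._add_param("w", _he_init(rng, (fan_in, out_ch), fan_in))
        self.b = self._add_param("b", np.zeros(out_ch, dtype=np.float32))
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def _index(self, hp, wp, oh, ow):
        key = (hp, wp, oh, ow)
        if key not in self._idx_cache:
            ohg, owg = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
            ih, iw = np.meshgrid(np.arange(self.kh), np.arange(self.kw),
                                 indexing="ij")
            rows = ohg.reshape(-1, 1) + ih.reshape(1, -1)   # (L, khkw)
            cols = owg.reshape(-1, 1) + iw.reshape(1, -1)
            flat = (rows * wp + cols)[:, :, None] * self.in_ch + \
                np.arange(self.in_ch)[None, None, :]
            idx = flat.reshape(flat.shape[0], -1)
            self._idx_cache[key] = (idx, build_scatter(idx, hp * wp * self.in_ch))
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} channels, got {c}")
        if self.padding == "same":
            ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        else:
            ph = pw = 0
        if h + 2 * ph < self.kh or w + 2 * pw < self.kw:
            raise ValueError(f"{self.name}: kernel larger than padded input")
        if ph or pw:
            x = x.pad(((0, 0), (ph, ph), (pw, pw), (0, 0)))
        hp, wp = h + 2 * ph, w + 2 * pw
        oh, ow = hp - self.kh + 1, wp - self.kw + 1
        idx, scatter = self._index(hp, wp, oh, ow)
        cols_t = x.reshape(n, hp * wp * self.in_ch).gather_cols(idx, scatter)
        out = cols_t @ self.w + self.b
        return out.reshape(n, oh, ow, self.out_ch)


class Conv3d(_Layer):
    """3-D convolution over (n, H, W, D, Cin): spatial same padding,
    spectral axis with configurable padding and stride."""

    def __init__(self, name, in_ch, out_ch, kernel, rng,
                 spectral_stride: int = 1, spectral_padding: str = "valid",
                 spatial_padding: str = "same"):
        super().__init__(name)
        self.kh, self.kw, self.kd = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.stride = spectral_stride
        self.spectral_padding = spectral_padding
        self.spatial_padding = spatial_padding
        fan_in = self.kh * self.kw * self.kd * in_ch
        self.w = self._add_param("w", _he_init(rng, (fan_in, out_ch), fan_in))
        self.b = self._add_param("b", np.zeros(out_ch, dtype=np.float32))
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def _index(self, hp, wp, dp, oh, ow, od):
        key = (hp, wp, dp, oh, ow, od)
        if key not in self._idx_cache:
            og = np.stack(np.meshgrid(np.arange(oh), np.arange(ow),
                                      np.arange(od), indexing="ij"),
                          axis=-1).reshape(-1, 3)             # (L, 3)
            kg = np.stack(np.meshgrid(np.arange(self.kh), np.arange(self.kw),
                                      np.arange(self.kd), indexing="ij"),
                          axis=-1).reshape(-1, 3)             # (Kk, 3)
            rows = og[:, 0:1] + kg[:, 0]
            cols = og[:, 1:2] + kg[:, 1]
            depth = og[:, 2:3] * self.stride + kg[:, 2]
            flat = ((rows * wp + cols) * dp + depth)[:, :, None] * self.in_ch \
                + np.arange(self.in_ch)[None, None, :]
            idx = flat.reshape(flat.shape[0], -1)
            self._idx_cache[key] = (idx,
                                    build_scatter(idx, hp * wp * dp * self.in_ch))
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, d, c = x.shape
        if c != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} channels, got {c}")
        if self.spatial_padding == "same":
            ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        else:
            ph = pw = 0
        pd = (self.kd - 1) // 2 if self.spectral_padding == "same" else 0
        if h + 2 * ph < self.kh or w + 2 * pw < self.kw or d + 2 * pd < self.kd:
            raise ValueError(f"{self.name}: spectral kernel {self.kd} cannot "
                             f"fit input depth {d}")
        if ph or pw or pd:
            x = x.pad(((0, 0), (ph, ph), (pw, pw), (pd, pd), (0, 0)))
        hp, wp, dp = h + 2 * ph, w + 2 * pw, d + 2 * pd
        oh, ow = hp - self.kh + 1, wp - self.kw + 1
        od = (dp - self.kd) // self.stride + 1
        idx, scatter = self._index(hp, wp, dp, oh, ow, od)
        cols_t = x.reshape(n, hp * wp * dp * self.in_ch).gather_cols(idx, scatter)
        out = cols_t @ self.w + self.b
        return out.reshape(n, oh, ow, od, self.out_ch)


class DepthwiseConv2d(_Layer):
    """Per-channel same-padded 2-D convolution (one k x k filter per channel)."""

    def __init__(self, name, channels, kernel, rng, trainable: bool = True,
                 weights: np.ndarray | None = None):
        super().__init__(name)
        k = kernel
        self.k, self.channels = k, channels
        if weights is None:
            weights = _he_init(rng, (k * k, channels), k * k)
        if trainable:
            self.w = self._add_param("w", weights)
            self.b = self._add_param("b", np.zeros(channels, dtype=np.float32))
        else:
            self.w = Tensor(weights)
            self.b = Tensor(np.zeros(channels, dtype=np.float32))
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def _index(self, hp, wp, oh, ow):
        key = (hp, wp, oh, ow)
        if key not in self._idx_cache:
            ohg, owg = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
            ih, iw = np.meshgrid(np.arange(self.k), np.arange(self.k),
                                 indexing="ij")
            rows = ohg.reshape(-1, 1) + ih.reshape(1, -1)
            cols = owg.reshape(-1, 1) + iw.reshape(1, -1)
            flat = (rows * wp + cols)[:, :, None] * self.channels + \
                np.arange(self.channels)[None, None, :]
            self._idx_cache[key] = (flat,
                                    build_scatter(flat, hp * wp * self.channels))
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        p = (self.k - 1) // 2
        x = x.pad(((0, 0), (p, p), (p, p), (0, 0)))
        hp, wp = h + 2 * p, w + 2 * p
        idx, scatter = self._index(hp, wp, h, w)
        cols_t = x.reshape(n, hp * wp * c).gather_cols(idx, scatter)  # (n, L, k*k, C)
        out = (cols_t * self.w.reshape(1, 1, self.k * self.k, c)).sum(axis=2)
        out = out + self.b
        return out.reshape(n, h, w, c)


class AvgPool2d(DepthwiseConv2d):
    """Stride-1 same-padded k x k average pool (fixed uniform depthwise)."""

    def __init__(self, name, channels, kernel):
        weights = np.full((kernel * kernel, channels), 1.0 / (kernel * kernel),
                          dtype=np.float32)
        super().__init__(name, channels, kernel, rng=None, trainable=False,
                         weights=weights)


class BatchNorm(_Layer):
    """Batch normalization over the trailing channel axis."""

    def __init__(self, name, channels, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__(name)
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = self._add_param("gamma", np.ones(channels, dtype=np.float32))
        self.beta = self._add_param("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if training and x.shape[0] == 1:
            warnings.warn(f"{self.name}: batch of size 1 in training mode; "
                          "using running statistics")
            training = False
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu).pow(2.0)).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(np.float32)
            xhat = (x - mu) * (var + self.eps).pow(-0.5)
        else:
            shape = (1,) * (x.ndim - 1) + (self.channels,)
            mu = Tensor(self.running_mean.reshape(shape))
            sd = Tensor(1.0 / np.sqrt(self.running_var + self.eps).reshape(shape))
            xhat = (x - mu) * sd
        return xhat * self.gamma + self.beta

    # running statistics travel with the checkpoints
    def state(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = np.asarray(state[f"{self.name}.running_mean"],
                                       dtype=np.float32)
        self.running_var = np.asarray(state[f"{self.name}.running_var"],
                                      dtype=np.float32)


class Linear(_Layer):
    def __init__(self, name, in_features, out_features, rng):
        super().__init__(name)
        self.w = self._add_param(
            "w", _he_init(rng, (in_features, out_features), in_features))
        self.b = self._add_param("b", np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class CBM(_Layer):
    """Convolution -> BatchNorm -> Smish unit (the sandglass tunnel's brick)."""

    def __init__(self, name, in_ch, out_ch, kernel, rng):
        super().__init__(name)
        self.conv = Conv2d(f"{name}.conv", in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm(f"{name}.bn", out_ch)
        self._params = self.conv._params + self.bn._params

    def forward(self, x: Tensor, training: bool) -> Tensor:
        return smish(self.bn.forward(self.conv.forward(x), training))

    def state(self):
        return self.bn.state()

    def load_state(self, state):
        self.bn.load_state(state)


class SandglassBlock(_Layer):
    """Inverted-bottleneck residual unit with depthwise convolutions at both
    ends and the shortcut between the high-dimensional representations:

        y = x + dw3x3 -> [reduce 1x1] -> [expand 1x1] -> dw3x3

    Smish follows the first depthwise and the expanding pointwise; batch
    norm follows every convolution.  Keeping depthwise convolutions in the
    wide representation is what lets the block encode spatial detail
    cheaply while the 1x1 pair squeezes channels through the bottleneck.
    """

    def __init__(self, name, width, ratio, rng):
        super().__init__(name)
        if width % ratio != 0:
            raise ValueError(f"width {width} not divisible by bottleneck "
                             f"ratio {ratio}")
        mid = width // ratio
        self.dw1 = DepthwiseConv2d(f"{name}.dw1", width, 3, rng)
        self.bn1 = BatchNorm(f"{name}.bn1", width)
        self.reduce = Conv2d(f"{name}.reduce", width, mid, 1, rng)
        self.bn2 = BatchNorm(f"{name}.bn2", mid)
        self.expand = Conv2d(f"{name}.expand", mid, width, 1, rng)
        self.bn3 = BatchNorm(f"{name}.bn3", width)
        self.dw2 = DepthwiseConv2d(f"{name}.dw2", width, 3, rng)
        self.bn4 = BatchNorm(f"{name}.bn4", width)
        self._subs = [self.dw1, self.bn1, self.reduce, self.bn2,
                      self.expand, self.bn3, self.dw2, self.bn4]
        self._params = [p for s in self._subs for p in s._params]

    def forward(self, x: Tensor, training: bool) -> Tensor:
        h = smish(self.bn1.forward(self.dw1.forward(x), training))
        h = self.bn2.forward(self.reduce.forward(h), training)
        h = smish(self.bn3.forward(self.expand.forward(h), training))
        h = self.bn4.forward(self.dw2.forward(h), training)
        return x + h

    def state(self):
        out = {}
        for bn in (self.bn1, self.bn2, self.bn3, self.bn4):
            out.update(bn.state())
        return out

    def load_state(self, state):
        for bn in (self.bn1, self.bn2, self.bn3, self.bn4):
            bn.load_state(state)


def global_avg_pool(x: Tensor) -> Tensor:
    """Average all spatial (and spectral) axes, keep (n, channels)."""
    axes = tuple(range(1, x.ndim - 1))
    return x.mean(axis=axes)
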