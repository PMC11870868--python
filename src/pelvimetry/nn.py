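"""Minimal numpy 3D convolutional network with manual backpropagation.

A deliberately small, dependency-free building block: 3x3x3 convolutions
via im2col + BLAS matmul, max pooling, nearest-neighbour upsampling,
skip concatenation and Adam. It exists to train the tiny 3D U-Net used
for heatmap regression on CPU in minutes; it is not a general deep
learning framework.

Arrays are float32 shaped (N, C, X, Y, Z). Gradients are stored on the
layers (``dW``, ``db``) after ``backward``.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError


class Conv3d:
    """Same-padded 3D convolution, He-initialized.

    ``ksize`` is a scalar or per-axis triple; each entry must be 1 or 3,
    so factorized anisotropic kernels like (3, 3, 1) are supported.
    """

    def __init__(self, cin: int, cout: int, ksize, rng: np.random.Generator,
                 dtype=np.float32):
        k = (ksize,) * 3 if np.isscalar(ksize) else tuple(int(v) for v in ksize)
        if any(v not in (1, 3) for v in k):
            raise ConfigError(f"kernel sizes must be 1 or 3 per axis, got {k}")
        self.cin, self.cout, self.k = cin, cout, k
        self.dtype = np.dtype(dtype)
        self.ktaps = k[0] * k[1] * k[2]
        fan_in = cin * self.ktaps
        self.weight = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            self.dtype
        )
        self.bias = np.zeros(cout, dtype=self.dtype)
        self.dW: Optional[np.ndarray] = None
        self.db: Optional[np.ndarray] = None
        self._col: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        pads = tuple(v // 2 for v in k)
        if any(pads):
            p0, p1, p2 = pads
            x = np.pad(x, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
        win = sliding_window_view(x, k, axis=(2, 3, 4))
        n, c = win.shape[0], win.shape[1]
        sx, sy, sz = win.shape[2:5]
        # (N, X, Y, Z, C*taps) rows, contiguous for matmul
        col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * sx * sy * sz, c * self.ktaps)
        return np.ascontiguousarray(col, dtype=self.dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        n, _, sx, sy, sz = x.shape
        col = self._im2col(x)
        self._col = col
        out = col @ self.weight.T + self.bias
        return out.reshape(n, sx, sy, sz, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._col is not None and self._xshape is not None
        n, _, sx, sy, sz = dout.shape
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 4, 1).reshape(-1, self.cout), dtype=self.dtype
        )
        self.dW = dflat.T @ self._col
        self.db = dflat.sum(axis=0)
        # grad wrt input = full correlation of dout with the flipped kernel
        k = self.k
        w = self.weight.reshape((self.cout, self.cin) + k)[:, :, ::-1, ::-1, ::-1]
        wprime = np.ascontiguousarray(
            w.transpose(0, 2, 3, 4, 1).reshape(self.cout * self.ktaps, self.cin)
        )
        pads = tuple(v // 2 for v in k)
        dpad = dout
        if any(pads):
            p0, p1, p2 = pads
            dpad = np.pad(dout, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
        win = sliding_window_view(dpad, k, axis=(2, 3, 4))
        dcol = np.ascontiguousarray(
            win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n * sx * sy * sz, self.cout * self.ktaps),
            dtype=self.dtype,
        )
        dx = (dcol @ wprime).reshape(n, sx, sy, sz, self.cin).transpose(0, 4, 1, 2, 3)
        self._col = None
        return np.ascontiguousarray(dx)

    @property
    def params(self) -> List[np.ndarray]:
        return [self.weight, self.bias]

    @property
    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]  # type: ignore[list-item]


class ReLU:
    """Leaky rectifier; the small negative slope keeps gradients alive in
    units that an aggressive step would otherwise switch off for good."""

    slope = 0.01

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._scale = np.where(x > 0, 1.0, self.slope).astype(x.dtype)
        return x * self._scale

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._scale


class MaxPool3d:
    """Max pooling with per-axis integer factors (anisotropy-aware)."""

    def __init__(self, factors: Sequence[int]):
        self.factors = tuple(int(f) for f in factors)
        if any(f < 1 for f in self.factors):
            raise ConfigError(f"pool factors must be >= 1: {self.factors}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        f0, f1, f2 = self.factors
        n, c, sx, sy, sz = x.shape
        if sx % f0 or sy % f1 or sz % f2:
            raise ConfigError(f"shape {x.shape[2:]} not divisible by pool {self.factors}")
        gx, gy, gz = sx // f0, sy // f1, sz // f2
        win = x.reshape(n, c, gx, f0, gy, f1, gz, f2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(n, c, gx, gy, gz, f0 * f1 * f2)
        self._argmax = win.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(win, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f0, f1, f2 = self.factors
        n, c, sx, sy, sz = self._inshape
        gx, gy, gz = sx // f0, sy // f1, sz // f2
        dwin = np.zeros((n, c, gx, gy, gz, f0 * f1 * f2), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, gx, gy, gz, f0, f1, f2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(dx.reshape(n, c, sx, sy, sz))


class Upsample3d:
    """Nearest-neighbour upsampling by per-axis factors."""

    def __init__(self, factors: Sequence[int]):
        self.factors = tuple(int(f) for f in factors)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f0, f1, f2 = self.factors
        out = np.repeat(x, f0, axis=2)
        out = np.repeat(out, f1, axis=3)
        return np.repeat(out, f2, axis=4)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        f0, f1, f2 = self.factors
        n, c, sx, sy, sz = dout.shape
        d = dout.reshape(n, c, sx // f0, f0, sy // f1, f1, sz // f2, f2)
        return d.sum(axis=(3, 5, 7))


class ConvBlock:
    """Factorized conv block: (3,3,1) in-plane then (1,1,3) through-slice.

    Splitting the 3x3x3 kernel roughly quarters the arithmetic while
    keeping the receptive field; voxels are ~6x thicker through-slice
    than in-plane, so the two passes see comparable physical extents.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.c1 = Conv3d(cin, cout, (3, 3, 1), rng, dtype)
        self.r1 = ReLU()
        self.c2 = Conv3d(cout, cout, (1, 1, 3), rng, dtype)
        self.r2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dout))))

    @property
    def convs(self) -> List[Conv3d]:
        return [self.c1, self.c2]


class UNet3D:
    """Tiny encoder-decoder with skip connections for heatmap regression.

    ``depth`` poolings halve the in-plane axes at every level; the slice
    axis is only pooled while its nominal size stays >= ``min_slice_pool``
    (anisotropy-aware: clinical volumes are ~16 slices deep). Input
    spatial shapes must be divisible by the cumulative pool product.
    """

    def __init__(
        self,
        in_channels: int = 1,
        out_channels: int = 5,
        base_channels: int = 8,
        depth: int = 2,
        nominal_patch: Sequence[int] = (128, 128, 16),
        min_slice_pool: int = 8,
        seed: int = 0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        self.depth = depth
        self.pool_factors: List[Tuple[int, int, int]] = []
        nz = int(nominal_patch[2])
        nx, ny = int(nominal_patch[0]), int(nominal_patch[1])
        for _ in range(depth):
            fz = 2 if (nz % 2 == 0 and nz >= min_slice_pool) else 1
            if nx % 2 or ny % 2 or nx < 4 or ny < 4:
                raise ConfigError(
                    f"patch {tuple(nominal_patch)} too small for depth {depth}"
                )
            self.pool_factors.append((2, 2, fz))
            nx, ny, nz = nx // 2, ny // 2, nz // fz

        self.enc: List[ConvBlock] = []
        self.pools: List[MaxPool3d] = []
        self.ups: List[Upsample3d] = []
        self.dec: List[ConvBlock] = []
        ch = in_channels
        enc_ch = []
        for l in range(depth):
            c = base_channels * 2**l
            self.enc.append(ConvBlock(ch, c, rng, dtype))
            self.pools.append(MaxPool3d(self.pool_factors[l]))
            enc_ch.append(c)
            ch = c
        cb = base_channels * 2**depth
        self.bottleneck = ConvBlock(ch, cb, rng, dtype)
        ch = cb
        for l in reversed(range(depth)):
            self.ups.insert(0, Upsample3d(self.pool_factors[l]))
            self.dec.insert(0, ConvBlock(ch + enc_ch[l], enc_ch[l], rng, dtype))
            ch = enc_ch[l]
        self.final = Conv3d(ch, out_channels, 1, rng, dtype)
        # start from the empty-heatmap prediction: stabilizes early training
        self.final.weight[:] = 0.0
        self.out_channels = out_channels
        self.in_channels = in_channels

    # -- shape bookkeeping -------------------------------------------------
    def required_multiple(self) -> Tuple[int, int, int]:
        m = np.ones(3, dtype=int)
        for f in self.pool_factors:
            m *= np.asarray(f)
        return tuple(int(v) for v in m)

    def _check_shape(self, shape: Tuple[int, ...]) -> None:
        m = self.required_multiple()
        if any(s % mi for s, mi in zip(shape, m)):
            raise ConfigError(f"input shape {shape} not divisible by {m}")

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check_shape(x.shape[2:])
        skips = []
        h = x.astype(self.dtype, copy=False)
        for l in range(self.depth):
            h = self.enc[l].forward(h)
            skips.append(h)
            h = self.pools[l].forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for l in reversed(range(self.depth)):
            h = self.ups[l].forward(h)
            h = np.concatenate([skips[l], h], axis=1)
            h = self.dec[l].forward(h)
        return self.final.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.final.backward(dout)
        dskips: List[np.ndarray] = [None] * self.depth  # type: ignore[list-item]
        for l in range(self.depth):
            d = self.dec[l].backward(d)
            cs = self._skip_channels[l]
            dskips[l] = d[:, :cs]
            d = self.ups[l].backward(d[:, cs:])
        d = self.bottleneck.backward(d)
        for l in reversed(range(self.depth)):
            d = self.pools[l].backward(d)
            d = d + dskips[l]
            d = self.enc[l].backward(d)
        return d

    # -- parameters --------------------------------------------------------
    def conv_layers(self) -> List[Conv3d]:
        layers: List[Conv3d] = []
        for b in self.enc:
            layers.extend(b.convs)
        layers.extend(self.bottleneck.convs)
        for b in self.dec:
            layers.extend(b.convs)
        layers.append(self.final)
        return layers

    def state_dict(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for layer in self.conv_layers():
            out.extend([layer.weight.copy(), layer.bias.copy()])
        return out

    def load_state_dict(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self.conv_layers():
            w, b = next(it), next(it)
            if w.shape != layer.weight.shape or b.shape != layer.bias.shape:
                raise ConfigError("checkpoint does not match network architecture")
            layer.weight = w.astype(layer.dtype).copy()
            layer.bias = b.astype(layer.dtype).copy()


class Adam:
    """Adam optimizer over the Conv3d layers of a network."""

    def __init__(self, layers: Sequence[Conv3d], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for l in self.layers for p in l.params]
        self._v = [np.zeros_like(p) for l in self.layers for p in l.params]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                m = self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
                v = self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff
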