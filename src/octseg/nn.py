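"""Minimal CPU convolutional-network library with explicit backpropagation.

Implements exactly the pieces the segmentation networks need: 2-D convolution
(optionally dilated) with replicate padding, ReLU, 2x2 max-pooling, nearest
upsampling, channel concatenation and an Adam optimizer.  Arrays are NCHW
float32; every layer caches its forward activations and `backward` consumes
the gradient of the loss w.r.t. its output, accumulating parameter gradients.

Replicate ("edge") padding is used instead of zero padding so a spatially
constant input stays constant through the whole stack — convenient both for
OCT (no artificial dark frame) and for sanity tests.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError

DTYPE = np.float32


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _fold_edge_padding(dxp: np.ndarray, p: int, h: int, w: int) -> np.ndarray:
    """Fold gradients of a replicate-padded array back onto the original
    pixels (padding rows/columns replicate the border, so their gradients
    accumulate there)."""
    if p == 0:
        return dxp
    dxr = dxp[:, :, p : p + h, :].copy()
    dxr[:, :, 0, :] += dxp[:, :, :p, :].sum(axis=2)
    dxr[:, :, -1, :] += dxp[:, :, p + h :, :].sum(axis=2)
    dx = dxr[:, :, :, p : p + w].copy()
    dx[:, :, :, 0] += dxr[:, :, :, :p].sum(axis=3)
    dx[:, :, :, -1] += dxr[:, :, :, p + w :].sum(axis=3)
    return dx


class Conv2d(Layer):
    """3x3 (or kxk) same-size convolution with replicate padding.

    ``dilation`` > 1 gives atrous convolution with an enlarged receptive
    field at unchanged output size.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        dilation: int = 1,
        rng: Optional[np.random.Generator] = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.weight = Param(
            rng.standard_normal((out_ch, in_ch, kernel, kernel)) * scale,
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_ch), name=f"{name}.bias")
        self.kernel = kernel
        self.dilation = dilation
        self.pad = dilation * (kernel // 2)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, d, p = self.kernel, self.dilation, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
        cols = np.empty((n, c, k, k, h, w), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i * d : i * d + h, j * d : j * d + w]
        cols = cols.reshape(n, c * k * k, h * w)
        wm = self.weight.value.reshape(self.weight.value.shape[0], -1)
        out = np.matmul(wm, cols) + self.bias.value[None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, d, p = self.kernel, self.dilation, self.pad
        out_ch = dout.shape[1]
        dout_f = dout.reshape(n, out_ch, h * w)
        wm = self.weight.value.reshape(out_ch, -1)
        dw = np.einsum("nof,ncf->oc", dout_f, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        dcols = np.matmul(wm.T, dout_f)  # (n, c*k*k, h*w)
        dcols = dcols.reshape(n, c, k, k, h, w)
        hp, wp = h + 2 * p, w + 2 * p
        dxp = np.zeros((n, c, hp, wp), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i * d : i * d + h, j * d : j * d + w] += dcols[:, :, i, j]
        return _fold_edge_padding(dxp, p, h, w)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; requires even spatial dimensions."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ConfigError("MaxPool2 needs even spatial dimensions")
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = np.argmax(flat, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dr = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return dout.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))


class ConvBlock(Layer):
    """Conv -> ReLU."""

    def __init__(self, in_ch, out_ch, rng, dilation=1, name="block"):
        self.conv = Conv2d(in_ch, out_ch, dilation=dilation, rng=rng, name=name)
        self.act = ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x):
        return self.act.forward(self.conv.forward(x))

    def backward(self, dout):
        return self.conv.backward(self.act.backward(dout))


class Module:
    """A network: forward caches everything backward needs."""

    def params(self) -> list[Param]:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # --- weight plumbing ----------------------------------------------------
    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ConfigError("weight structure mismatch")
        for p, w in zip(own, weights):
            if p.value.shape != np.shape(w):
                raise ConfigError(
                    f"weight shape mismatch for {p.name}: "
                    f"{p.value.shape} vs {np.shape(w)}"
                )
            p.value = np.asarray(w, dtype=DTYPE).copy()


class UNet(Module):
    """Small encoder-decoder with skip connections (one conv per stage)."""

    def __init__(self, in_ch: int, n_classes: int, width: int = 8, depth: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        ch = in_ch
        widths = [width * (2**i) for i in range(depth)]
        for i, wd in enumerate(widths):
            self.enc.append(ConvBlock(ch, wd, rng, name=f"enc{i}"))
            self.pools.append(MaxPool2())
            ch = wd
        self.bottleneck = ConvBlock(ch, width * (2**depth), rng, name="bottleneck")
        ch = width * (2**depth)
        self.ups: list[Upsample2] = []
        self.dec: list[ConvBlock] = []
        for i in reversed(range(depth)):
            self.ups.append(Upsample2())
            self.dec.append(ConvBlock(ch + widths[i], widths[i], rng, name=f"dec{i}"))
            ch = widths[i]
        self.head = Conv2d(ch, n_classes, kernel=1, rng=rng, name="head")

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x)
        return self.head.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(np.asarray(dout, dtype=DTYPE))
        dskips = []
        for up, blk, upch in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)
        ):
            d = blk.backward(d)
            d_up, d_skip = d[:, :upch], d[:, upch:]
            dskips.append(d_skip)
            d = up.backward(d_up)
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for blk, pool, d_skip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + d_skip
            d = blk.backward(d)
        return d


class DilatedEncDec(Module):
    """Encoder-decoder with dilated (atrous) convolutions and no pooling:
    a compact stand-in for DeepLab-style context aggregation."""

    def __init__(self, in_ch: int, n_classes: int, width: int = 8, depth: int = 2,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        dilations = [1, 2, 4, 8]
        self.blocks: list[ConvBlock] = []
        ch = in_ch
        n_blocks = max(depth + 1, 2)
        for i in range(n_blocks):
            d = dilations[min(i, len(dilations) - 1)]
            self.blocks.append(ConvBlock(ch, width, rng, dilation=d, name=f"ctx{i}"))
            ch = width
        self.decoder = ConvBlock(ch, width, rng, dilation=1, name="dec")
        self.head = Conv2d(width, n_classes, kernel=1, rng=rng, name="head")

    def params(self):
        ps = []
        for blk in self.blocks:
            ps += blk.params()
        ps += self.decoder.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for blk in self.blocks:
            x = blk.forward(x)
        x = self.decoder.forward(x)
        return self.head.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(np.asarray(dout, dtype=DTYPE))
        d = self.decoder.backward(d)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        return d


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
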