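"""Plain 2D U-Net regressor: depth-D encoder/decoder with skip connections,
two 3x3 conv + ReLU blocks per level, nearest upsampling, linear 1x1 output.

Input height/width must be divisible by ``2**depth``.  Weights are float32;
initialization, and therefore training, is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2D, MaxPool2, ReLU, UpsampleNearest2

__all__ = ["UNet2D"]

F32 = np.float32


class _DoubleConv:
    def __init__(self, c_in, c_out, rng):
        self.conv1 = Conv2D(c_in, c_out, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c_out, c_out, 3, rng)
        self.relu2 = ReLU()

    def forward(self, x, train=True):
        x = self.relu1.forward(self.conv1.forward(x, train), train)
        return self.relu2.forward(self.conv2.forward(x, train), train)

    def backward(self, d):
        d = self.conv2.backward(self.relu2.backward(d))
        return self.conv1.backward(self.relu1.backward(d))

    @property
    def convs(self):
        return [self.conv1, self.conv2]


class UNet2D:
    def __init__(self, depth: int = 3, base_filters: int = 16, seed: int = 0,
                 in_channels: int = 1, out_channels: int = 1):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_filters = base_filters
        ch = [base_filters * (2**d) for d in range(depth + 1)]

        self.enc = []
        c_in = in_channels
        for d in range(depth):
            self.enc.append(_DoubleConv(c_in, ch[d], rng))
            c_in = ch[d]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _DoubleConv(ch[depth - 1], ch[depth], rng)

        self.ups = [UpsampleNearest2() for _ in range(depth)]
        self.upconvs = []   # 3x3 conv halving channels after upsampling
        self.upconv_relus = [ReLU() for _ in range(depth)]
        self.dec = []       # double conv after skip concatenation
        for d in reversed(range(depth)):
            self.upconvs.append(Conv2D(ch[d + 1], ch[d], 3, rng))
            self.dec.append(_DoubleConv(2 * ch[d], ch[d], rng))
        self.final = Conv2D(ch[0], out_channels, 1, rng)
        self._concat_ch = [ch[d] for d in reversed(range(depth))]

    # -- parameter plumbing -------------------------------------------
    def _all_convs(self):
        convs = []
        for blk in self.enc:
            convs += blk.convs
        convs += self.bottleneck.convs
        for up, blk in zip(self.upconvs, self.dec):
            convs.append(up)
            convs += blk.convs
        convs.append(self.final)
        return convs

    @property
    def params(self):
        return [p for c in self._all_convs() for p in c.params]

    @property
    def grads(self):
        return [g for c in self._all_convs() for g in c.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w.astype(F32)

    @property
    def receptive_field_radius(self) -> int:
        """Half-width of the input window influencing one output pixel."""
        rf = 1
        for d in range(self.depth):       # encoder double convs
            rf += 2 * 2 * (2**d)
        rf += 2 * 2 * (2**self.depth)     # bottleneck
        for d in reversed(range(self.depth)):  # upconv + decoder double conv
            rf += 3 * 2 * (2**d)
        return (rf - 1) // 2 + 1

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=F32)
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        m = 2**self.depth
        if x.shape[2] % m or x.shape[3] % m:
            raise ValueError(
                f"input H/W must be divisible by {m}, got {x.shape[2:]}"
            )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, upconv, urelu, blk, skip in zip(
            self.ups, self.upconvs, self.upconv_relus, self.dec, reversed(skips)
        ):
            x = urelu.forward(upconv.forward(up.forward(x, train), train), train)
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        return self.final.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.final.backward(np.ascontiguousarray(dout, dtype=F32))
        dskips = []
        for up, upconv, urelu, blk, c_skip in zip(
            reversed(self.ups), reversed(self.upconvs), reversed(self.upconv_relus),
            reversed(self.dec), self._concat_ch[::-1],
        ):
            d = blk.backward(d)
            dskip, d = d[:, :c_skip], d[:, c_skip:]
            dskips.append(dskip)
            d = up.backward(upconv.backward(urelu.backward(d)))
        d = self.bottleneck.backward(d)
        # dskips[i] holds the gradient for skips[i]; encoder unwinds deepest-first
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            d = blk.backward(d)
        return d
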