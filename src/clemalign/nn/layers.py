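"""Layer primitives with explicit forward/backward passes.

Data layout is NCHW float32 throughout.  Each layer caches what its backward
pass needs; ``backward`` consumes the upstream gradient and returns the
gradient with respect to the input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "MaxPool2", "UpsampleNearest2"]

F32 = np.float32


class Conv2D:
    """Same-padded 2D convolution (kernel 3 or 1), He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, int, int] | None = None

    @property
    def params(self):
        return [self.w, self.b]

    @property
    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if self.kernel == 1:
            cols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n,c,h,w,3,3
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * h * w, c * 9
            )
        if train:
            self._cols = cols
            self._shape = (n, h, w)
        out = cols @ self.w.T + self.b
        return np.ascontiguousarray(out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._shape is not None
        n, h, w = self._shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.c_out)
        self.dw[...] = dmat.T @ self._cols
        self.db[...] = dmat.sum(axis=0)
        dcols = dmat @ self.w
        self._cols = None
        if self.kernel == 1:
            return np.ascontiguousarray(
                dcols.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
            )
        dcols = dcols.reshape(n, h, w, self.c_in, 3, 3).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, self.c_in, h + 2, w + 2), dtype=F32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        return dxp[:, :, 1:-1, 1:-1]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2 (input H and W must be even)."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = np.ascontiguousarray(v).reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._idx is not None and self._shape is not None
        n, c, h, w = self._shape
        dv = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dv, self._idx[..., None], dout[..., None], axis=-1)
        dx = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class UpsampleNearest2:
    """Nearest-neighbor 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return (
            dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(F32)
        )
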