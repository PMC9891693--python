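"""Minimal 3D layers with explicit forward/backward passes (float32, numpy).

No autograd framework is available in the runtime environment, so every
layer caches what its backward pass needs and returns the gradient with
respect to its input; convolution gradients additionally accumulate into
``dw``/``db``.  Tensors are channel-first: (C, D, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3d", "ELU", "MaxPool2", "NearestUpsample2", "softmax", "softmax_backward"]


class Conv3d:
    """Stride-1, same-padding 3D convolution (kernel 1 or 3 per axis)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int, int],
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.kernel = c_in, c_out, tuple(kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("kernels must be odd for same padding")
        fan_in = c_in * int(np.prod(self.kernel))
        # He initialization suits the ELU-activated stack
        self.w = (rng.standard_normal((c_out, c_in, *self.kernel)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._windows = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pads = [(0, 0)] + [(k // 2, k // 2) for k in self.kernel]
        xp = np.pad(x, pads)
        win = sliding_window_view(xp, self.kernel, axis=(1, 2, 3))
        self._windows = win  # view into xp; kept for the weight gradient
        out = np.tensordot(win, self.w, axes=([0, 4, 5, 6], [1, 2, 3, 4]))
        out = np.moveaxis(out, -1, 0) + self.b[:, None, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._windows
        # dW[o,c,i,j,l] = sum_dhw dout[o,d,h,w] * win[c,d,h,w,i,j,l]
        self.dw += np.tensordot(dout, win, axes=([1, 2, 3], [1, 2, 3]))
        self.db += dout.sum(axis=(1, 2, 3))
        # dx: correlate padded dout with the flipped kernel
        pads = [(0, 0)] + [(k // 2, k // 2) for k in self.kernel]
        doutp = np.pad(dout, pads)
        win_d = sliding_window_view(doutp, self.kernel, axis=(1, 2, 3))
        wflip = self.w[:, :, ::-1, ::-1, ::-1]
        dx = np.tensordot(win_d, wflip, axes=([0, 4, 5, 6], [0, 2, 3, 4]))
        dx = np.moveaxis(dx, -1, 0)
        self._windows = None
        return np.ascontiguousarray(dx, dtype=np.float32)

    def zero_grad(self):
        self.dw[...] = 0
        self.db[...] = 0


class ELU:
    """Exponential linear unit, alpha = 1."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._out = out
        self._pos = x > 0
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        grad = np.where(self._pos, 1.0, self._out + 1.0)
        return (dout * grad).astype(np.float32)


class MaxPool2:
    """2x2x2 max pooling; requires even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape}")
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = dout.shape
        grad = np.zeros((c, d2, h2, w2, 8), dtype=np.float32)
        np.put_along_axis(grad, self._arg[..., None], dout[..., None], axis=-1)
        grad = grad.reshape(c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return grad.reshape(self._in_shape)


class NearestUpsample2:
    """Nearest-neighbor 2x upsampling; the adjoint is block summation."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d, h, w = dout.shape
        return (dout.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
                .sum(axis=(2, 4, 6)).astype(np.float32))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-wise softmax over axis 0."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient through softmax: dlogits = p * (dp - sum(dp * p))."""
    inner = (dp * p).sum(axis=0, keepdims=True)
    return (p * (dp - inner)).astype(np.float32)
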