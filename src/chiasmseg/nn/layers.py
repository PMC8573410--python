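"""NumPy building blocks of the 3D U-Net with explicit forward/backward.

All tensors use the layout (N, C, D, H, W) in float32.  Each layer caches
what its backward pass needs during forward; backward returns the gradient
with respect to the input and accumulates parameter gradients in ``grads``.
Convolutions are evaluated as chunked im2col matrix products so peak memory
stays bounded at full-brain sizes (160^3).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "BatchNorm3d",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "softmax_channels",
    "softmax_backward",
]

def _conv3d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3x3 'same' convolution (cross-correlation), stride 1, no bias.

    Evaluated as 27 accumulated GEMMs over spatially shifted views, which is
    far more cache-friendly than an explicit im2col patch tensor.
    """
    n_b, c_in, d, h, wd = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros((n_b, c_out, d * h * wd), dtype=x.dtype)
    w = w.astype(x.dtype, copy=False)
    for a in range(3):
        for b in range(3):
            for c in range(3):
                sub = np.ascontiguousarray(
                    xp[:, :, a : a + d, b : b + h, c : c + wd]
                ).reshape(n_b, c_in, -1)
                out += w[:, :, a, b, c] @ sub
    return out.reshape(n_b, c_out, d, h, wd)


def _conv3d_grad_w(x: np.ndarray, gy: np.ndarray, w_shape) -> np.ndarray:
    """Gradient of the 'same' convolution with respect to the kernel."""
    n_b, c_in, d, h, wd = x.shape
    c_out = gy.shape[1]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    gy_mat = gy.reshape(n_b, c_out, -1)
    gw = np.zeros(w_shape, dtype=np.float64)
    for a in range(3):
        for b in range(3):
            for c in range(3):
                sub = np.ascontiguousarray(
                    xp[:, :, a : a + d, b : b + h, c : c + wd]
                ).reshape(n_b, c_in, -1)
                acc = np.zeros((c_out, c_in), dtype=np.float64)
                for n in range(n_b):
                    acc += gy_mat[n] @ sub[n].T
                gw[:, :, a, b, c] = acc
    return gw.astype(x.dtype)


class Conv3x3:
    """3x3x3 convolution, padding 1, no bias (normalization follows)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (c_in * 27))  # He-uniform fan-in
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in, 3, 3, 3)).astype(np.float32)
        self.gw = np.zeros_like(self.w)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return {"w": self.w}

    @property
    def grads(self):
        return {"w": self.gw}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return _conv3d_same(x, self.w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw = _conv3d_grad_w(self._x, gy, self.w.shape)
        # input gradient = full correlation with the spatially flipped,
        # channel-transposed kernel
        w_t = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _conv3d_same(gy, np.ascontiguousarray(w_t))


class Conv1x1:
    """1x1x1 convolution with bias (the two-channel output head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / c_in)
        self.w = rng.uniform(-bound, bound, size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    @property
    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        out = np.einsum("ncdhw,oc->nodhw", x, self.w, optimize=True)
        return out + self.b[None, :, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw = np.einsum("nodhw,ncdhw->oc", gy, self._x, optimize=True)
        self.gb = gy.sum(axis=(0, 2, 3, 4))
        return np.einsum("nodhw,oc->ncdhw", gy, self.w, optimize=True)


class BatchNorm3d:
    """Per-channel batch normalization with learnable scale and shift.

    Running statistics are tracked for inference only and are not counted
    as trainable parameters.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    @property
    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    @property
    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean[None, :, None, None, None]) / std[None, :, None, None, None]
        if train:
            self._cache = (xhat, std)
        return self.gamma[None, :, None, None, None] * xhat + self.beta[
            None, :, None, None, None
        ]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, std = self._cache
        axes = (0, 2, 3, 4)
        m = gy.size / gy.shape[1]
        self.ggamma = (gy * xhat).sum(axis=axes)
        self.gbeta = gy.sum(axis=axes)
        coeff = (self.gamma / std)[None, :, None, None, None] / m
        return (
            coeff
            * (
                m * gy
                - self.gbeta[None, :, None, None, None]
                - xhat * self.ggamma[None, :, None, None, None]
            )
        ).astype(gy.dtype)


class ReLU:
    def __init__(self):
        self._mask = None
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool2:
    """2x2x2 max pooling with stride 2."""

    def __init__(self):
        self._cache = None
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2x2 pooling, got {x.shape}")
        r = (
            x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d // 2, h // 2, w // 2, 8)
        )
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        n, c, d, h, w = shape
        flat = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(flat, idx[..., None], gy[..., None], axis=-1)
        return (
            flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(shape)
        )


class UpConv2:
    """2x2x2 transposed convolution, stride 2, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (c_in * 8))
        self.w = rng.uniform(-bound, bound, size=(c_in, c_out, 2, 2, 2)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return {"w": self.w, "b": self.b}

    @property
    def grads(self):
        return {"w": self.gw, "b": self.gb}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        n, ci, d, h, w = x.shape
        co = self.w.shape[1]
        t = np.tensordot(x, self.w, axes=([1], [0]))  # (N,D,H,W,Co,2,2,2)
        out = (
            t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(n, co, 2 * d, 2 * h, 2 * w)
        )
        return (out + self.b[None, :, None, None, None]).astype(x.dtype)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        n, ci, d, h, w = x.shape
        co = self.w.shape[1]
        gt = (
            gy.reshape(n, co, d, 2, h, 2, w, 2).transpose(0, 2, 4, 6, 1, 3, 5, 7)
        )  # (N,D,H,W,Co,2,2,2)
        self.gw = np.tensordot(x, gt, axes=([0, 2, 3, 4], [0, 1, 2, 3])).astype(
            np.float32
        )
        self.gb = gy.sum(axis=(0, 2, 3, 4))
        gx = np.tensordot(gt, self.w, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        return gx.transpose(0, 4, 1, 2, 3).astype(gy.dtype)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis (axis 1)."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(p: np.ndarray, gp: np.ndarray) -> np.ndarray:
    """Gradient wrt logits given probabilities ``p`` and dL/dp ``gp``."""
    dot = (p * gp).sum(axis=1, keepdims=True)
    return p * (gp - dot)
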