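"""Minimal deterministic 3D neural-network layers on numpy.

Array layout is channels-first with a batch axis: ``(N, C, X, Y, Z)``.
Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into :class:`Param.grad` during
``backward``.  Everything is float32 and driven by explicit
``numpy.random.Generator`` seeds, so training runs are bit-reproducible
on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "ReLU",
    "Dropout",
    "softmax_channels",
    "softmax_cross_entropy",
    "weighted_cross_entropy",
    "soft_dice_loss",
]


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride 1, shape-preserving ("same") zero padding.

    Odd kernel sizes only (1 or 3 in this package).  He-normal weight
    initialization from the supplied generator.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv"):
        if kernel_size % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size**3
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0.0, std, size=(out_channels, in_channels, self.k, self.k, self.k)),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias")
        self.name = name
        self._x_pad: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        p, k = self.pad, self.k
        x = np.asarray(x, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        self._x_pad = xp if train else None
        n = x.shape[0]
        sx, sy, sz = x.shape[2:]
        w = self.weight.value
        # shift-and-accumulate: one (C_in → C_out) contraction per kernel offset
        y = np.zeros((n, self.out_channels, sx, sy, sz), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = xp[:, :, a : a + sx, b : b + sy, c : c + sz]
                    y += np.einsum("ncxyz,oc->noxyz", xs, w[:, :, a, b, c], optimize=True)
        y += self.bias.value[None, :, None, None, None]
        return y

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._x_pad is None:
            raise RuntimeError("backward called without a train-mode forward")
        k, p = self.k, self.pad
        xp = self._x_pad
        n, _, sx, sy, sz = grad_out.shape
        w = self.weight.value
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w)
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    xs = xp[:, :, a : a + sx, b : b + sy, c : c + sz]
                    dw[:, :, a, b, c] = np.einsum("noxyz,ncxyz->oc", grad_out, xs, optimize=True)
                    dxp[:, :, a : a + sx, b : b + sy, c : c + sz] += np.einsum(
                        "noxyz,oc->ncxyz", grad_out, w[:, :, a, b, c], optimize=True
                    )
        self.weight.grad += dw
        self.bias.grad += grad_out.sum(axis=(0, 2, 3, 4)).astype(np.float32, copy=False)
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        return np.ascontiguousarray(dxp)


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2, stride 2 (exact ×2 upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 name: str = "upconv"):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 8
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.normal(0.0, std, size=(in_channels, out_channels, 2, 2, 2)),
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(out_channels), name=f"{name}.bias")
        self.name = name
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        n, _, sx, sy, sz = x.shape
        t = np.einsum("nixyz,ioabc->noxaybzc", x, self.weight.value, optimize=True)
        y = t.reshape(n, self.out_channels, 2 * sx, 2 * sy, 2 * sz)
        y = y + self.bias.value[None, :, None, None, None]
        return np.ascontiguousarray(y).astype(np.float32, copy=False)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called without a train-mode forward")
        n, o, gx, gy, gz = grad_out.shape
        g = grad_out.reshape(n, o, gx // 2, 2, gy // 2, 2, gz // 2, 2)
        dw = np.einsum("nixyz,noxaybzc->ioabc", self._x, g, optimize=True)
        self.weight.grad += dw.astype(np.float32, copy=False)
        self.bias.grad += grad_out.sum(axis=(0, 2, 3, 4)).astype(np.float32, copy=False)
        dx = np.einsum("noxaybzc,ioabc->nixyz", g, self.weight.value, optimize=True)
        return np.ascontiguousarray(dx).astype(np.float32, copy=False)


class MaxPool3d(Layer):
    """2×2×2 max pooling with stride 2; ties route to the first maximum."""

    def __init__(self):
        self._argmax: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        n, c, sx, sy, sz = x.shape
        if sx % 2 or sy % 2 or sz % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {(sx, sy, sz)}")
        r = x.reshape(n, c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
        flat = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, sx // 2, sy // 2, sz // 2, 8)
        if train:
            self._argmax = flat.argmax(axis=-1)
            self._in_shape = x.shape
        return np.ascontiguousarray(flat.max(axis=-1))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._argmax is None:
            raise RuntimeError("backward called without a train-mode forward")
        n, c, hx, hy, hz = grad_out.shape
        scatter = np.zeros((n, c, hx, hy, hz, 8), dtype=np.float32)
        np.put_along_axis(scatter, self._argmax[..., None], grad_out[..., None], axis=-1)
        scatter = scatter.reshape(n, c, hx, hy, hz, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(scatter.reshape(self._in_shape))


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a train-mode forward")
        return grad_out * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode and at rate 0."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None  # set by the owning model
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None if not train else np.ones(1, dtype=np.float32)
            self._identity = True
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in train mode without an RNG attached")
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        self._identity = False
        return x * mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            raise RuntimeError("backward called without a train-mode forward")
        if self._identity:
            return grad_out
        return grad_out * self._mask


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the channel axis (axis 1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-voxel categorical cross-entropy and its logit gradient.

    ``logits`` is ``(N, C, X, Y, Z)``; ``target`` is ``(N, X, Y, Z)``
    integer class indices.  The returned gradient is already divided by
    the number of voxels (mean reduction).
    """
    probs = softmax_channels(logits)
    n, c = logits.shape[:2]
    flat_p = probs.reshape(n, c, -1)
    flat_t = target.reshape(n, -1)
    idx_n = np.arange(n)[:, None]
    idx_v = np.arange(flat_t.shape[1])[None, :]
    picked = flat_p[idx_n, flat_t, idx_v]
    n_vox = flat_t.size
    loss = float(-np.log(np.clip(picked, 1e-12, None)).sum() / n_vox)
    onehot = np.zeros_like(flat_p)
    onehot[idx_n, flat_t, idx_v] = 1.0
    dlogits = (flat_p - onehot).reshape(logits.shape) / n_vox
    return loss, dlogits.astype(np.float32, copy=False)


def weighted_cross_entropy(
    logits: np.ndarray, target: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Per-voxel cross-entropy with per-class weights, normalized by the
    total voxel weight; gradient through the softmax included.

    Class weights rebalance the gradient signal when foreground classes
    occupy a small voxel fraction (the norm in tumor segmentation).
    """
    probs = softmax_channels(logits)
    n, c = logits.shape[:2]
    w = np.asarray(class_weights, dtype=np.float32)
    if w.shape != (c,):
        raise ValueError(f"class_weights must have shape ({c},), got {w.shape}")
    flat_p = probs.reshape(n, c, -1)
    flat_t = target.reshape(n, -1)
    idx_n = np.arange(n)[:, None]
    idx_v = np.arange(flat_t.shape[1])[None, :]
    w_vox = w[flat_t]
    picked = flat_p[idx_n, flat_t, idx_v]
    w_sum = float(w_vox.sum())
    loss = float(-(w_vox * np.log(np.clip(picked, 1e-12, None))).sum() / w_sum)
    onehot = np.zeros_like(flat_p)
    onehot[idx_n, flat_t, idx_v] = 1.0
    dlogits = ((flat_p - onehot) * w_vox[:, None, :]).reshape(logits.shape) / w_sum
    return loss, dlogits.astype(np.float32, copy=False)


def soft_dice_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """1 − soft Dice over flattened one-hot classes, with logit gradient.

    Uses the global formulation ``2·Σ(p·t) / (Σp² + Σt²)`` per batch,
    averaged over classes; gradient derived analytically through the
    softmax.
    """
    probs = softmax_channels(logits)
    n, c = logits.shape[:2]
    p = probs.reshape(n, c, -1)
    t_idx = target.reshape(n, -1)
    t = np.zeros_like(p)
    t[np.arange(n)[:, None], t_idx, np.arange(t_idx.shape[1])[None, :]] = 1.0
    inter = (p * t).sum(axis=(0, 2))
    denom = (p * p).sum(axis=(0, 2)) + (t * t).sum(axis=(0, 2)) + eps
    dice_c = (2.0 * inter + eps) / denom
    loss = float(1.0 - dice_c.mean())
    # d(dice_c)/dp = (2t*denom - (2inter+eps)*2p) / denom^2, then through softmax
    dp = -(2.0 * t * denom[None, :, None] - (2.0 * inter + eps)[None, :, None] * 2.0 * p) / (
        denom[None, :, None] ** 2
    ) / c
    # softmax jacobian: dL/dz_k = p_k (dp_k - sum_j dp_j p_j)
    dot = (dp * p).sum(axis=1, keepdims=True)
    dlogits = (p * (dp - dot)).reshape(logits.shape)
    return loss, dlogits.astype(np.float32, copy=False)
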