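"""Model containers: a common segmentation-model contract and the 3D U-Net.

A :class:`SegmentationModel` is the opaque trainable handle the rest of
the pipeline works with.  It guarantees:

* ``forward(x)`` on ``(N, C_in, X, Y, Z)`` returns per-voxel class
  probabilities ``(N, n_classes, X, Y, Z)`` summing to 1 over channels;
* named-layer access for explainability and output-stripping
  (``activation_names``, capture of activations and their gradients);
* exact weight snapshot/restore for checkpointing.

The backward pass is wired manually (the graphs are small and static),
which makes gradient capture at any named activation trivial.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Conv3d,
    ConvTranspose3d,
    Dropout,
    Layer,
    MaxPool3d,
    Param,
    ReLU,
    softmax_channels,
)

__all__ = ["SegmentationModel", "ConvBlock", "UNet3D"]


class ConvBlock:
    """conv(k³) → ReLU → conv(k³) → ReLU [→ dropout].

    The block's named activations are ``<name>.conv1`` and
    ``<name>.conv2`` — the post-ReLU feature maps of each convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, name: str, dropout_rate: float = 0.0):
        self.name = name
        self.conv1 = Conv3d(in_channels, out_channels, kernel_size, rng, f"{name}.conv1")
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, kernel_size, rng, f"{name}.conv2")
        self.relu2 = ReLU()
        self.dropout = Dropout(dropout_rate) if dropout_rate > 0 else None
        self.out_channels = out_channels

    def parameters(self) -> list[Param]:
        return self.conv1.parameters() + self.conv2.parameters()

    def layers(self) -> list[Layer]:
        out = [self.conv1, self.relu1, self.conv2, self.relu2]
        if self.dropout is not None:
            out.append(self.dropout)
        return out

    def forward(self, x, *, train=False, acts=None, capture=()):
        h = self.relu1.forward(self.conv1.forward(x, train=train), train=train)
        if acts is not None and f"{self.name}.conv1" in capture:
            acts[f"{self.name}.conv1"] = h
        h = self.relu2.forward(self.conv2.forward(h, train=train), train=train)
        if acts is not None and f"{self.name}.conv2" in capture:
            acts[f"{self.name}.conv2"] = h
        if self.dropout is not None:
            h = self.dropout.forward(h, train=train)
        return h

    def backward(self, grad, *, grads=None, capture=()):
        if self.dropout is not None:
            grad = self.dropout.backward(grad)
        if grads is not None and f"{self.name}.conv2" in capture:
            grads[f"{self.name}.conv2"] = grad
        grad = self.conv2.backward(self.relu2.backward(grad))
        if grads is not None and f"{self.name}.conv1" in capture:
            grads[f"{self.name}.conv1"] = grad
        return self.conv1.backward(self.relu1.backward(grad))


class SegmentationModel:
    """Base contract: parameters, snapshots, named-activation capture."""

    n_classes: int
    in_channels: int

    def parameters(self) -> list[Param]:  # pragma: no cover
        raise NotImplementedError

    def forward_logits(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def activation_names(self) -> list[str]:  # pragma: no cover
        raise NotImplementedError

    def forward(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        """Per-voxel class probabilities (softmax over channel axis)."""
        return softmax_channels(self.forward_logits(x, train=train))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            w = np.asarray(w, dtype=np.float32)
            if w.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}: {w.shape} != {p.value.shape}")
            p.value = w.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # --- named-activation capture (forward values and backward grads) ---
    def request_capture(self, names) -> None:
        unknown = set(names) - set(self.activation_names)
        if unknown:
            raise KeyError(f"unknown activation name(s) {sorted(unknown)}; "
                           f"available: {self.activation_names}")
        self._capture = tuple(names)
        self.activations: dict[str, np.ndarray] = {}
        self.captured_grads: dict[str, np.ndarray] = {}

    def clear_capture(self) -> None:
        self._capture = ()
        self.activations = {}
        self.captured_grads = {}

    def _dropout_layers(self) -> list[Dropout]:
        return []

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for d in self._dropout_layers():
            d.rng = rng


class UNet3D(SegmentationModel):
    """Symmetric encoder-decoder 3D U-Net with skip connections.

    ``depth_levels`` resolution stages (the deepest is the bottleneck),
    two 3³ convolutions + ReLU per stage, 2× max-pool downsampling,
    filters doubling from ``base_filters``; transposed-conv upsampling
    with skip concatenation on the decoder; dropout at the bottleneck
    and decoder stages; final 1³ convolution to ``n_classes``.

    Spatial input dims must be divisible by ``2**(depth_levels-1)``.
    """

    def __init__(self, in_channels: int, n_classes: int = 4, depth_levels: int = 4,
                 base_filters: int = 16, dropout_rate: float = 0.2,
                 kernel_size: int = 3, seed: int = 0):
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth_levels = depth_levels
        self.base_filters = base_filters
        self.dropout_rate = dropout_rate
        self.kernel_size = kernel_size
        self.seed = seed
        rng = np.random.default_rng(seed)

        L = depth_levels
        f = [base_filters * 2**i for i in range(L)]
        self.enc_blocks = [
            ConvBlock(in_channels if i == 0 else f[i - 1], f[i], kernel_size, rng, f"enc{i}")
            for i in range(L - 1)
        ]
        self.pools = [MaxPool3d() for _ in range(L - 1)]
        self.bottleneck = ConvBlock(f[L - 2] if L > 1 else in_channels, f[L - 1],
                                    kernel_size, rng, "bottleneck", dropout_rate)
        self.upconvs = [ConvTranspose3d(f[i + 1], f[i], rng, f"up{i}") for i in range(L - 1)]
        self.dec_blocks = [
            ConvBlock(2 * f[i], f[i], kernel_size, rng, f"dec{i}", dropout_rate)
            for i in range(L - 1)
        ]
        self.out_conv = Conv3d(f[0], n_classes, 1, rng, "out_conv")
        self._capture: tuple = ()
        self.activations: dict[str, np.ndarray] = {}
        self.captured_grads: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    # ------------------------------------------------------------------
    @property
    def activation_names(self) -> list[str]:
        names = []
        for blk in self.enc_blocks + [self.bottleneck] + self.dec_blocks:
            names += [f"{blk.name}.conv1", f"{blk.name}.conv2"]
        names.append("out_conv")
        return names

    @property
    def penultimate_channels(self) -> int:
        return self.base_filters

    @property
    def layer_channels(self) -> dict[str, int]:
        d = {}
        for blk in self.enc_blocks + [self.bottleneck] + self.dec_blocks:
            d[f"{blk.name}.conv1"] = blk.out_channels
            d[f"{blk.name}.conv2"] = blk.out_channels
        d["out_conv"] = self.n_classes
        return d

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for blk in self.enc_blocks:
            params += blk.parameters()
        params += self.bottleneck.parameters()
        for up, dec in zip(self.upconvs, self.dec_blocks):
            params += up.parameters() + dec.parameters()
        params += self.out_conv.parameters()
        return params

    def _dropout_layers(self):
        out = []
        for blk in [self.bottleneck] + self.dec_blocks:
            if blk.dropout is not None:
                out.append(blk.dropout)
        return out

    # ------------------------------------------------------------------
    def _check_spatial(self, x: np.ndarray) -> None:
        if x.ndim != 5:
            raise ValueError(f"expected input (N, C, X, Y, Z), got shape {x.shape}")
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[1]}")
        div = 2 ** (self.depth_levels - 1)
        bad = [s for s in x.shape[2:] if s % div]
        if bad:
            raise ValueError(
                f"spatial dims {x.shape[2:]} must each be divisible by {div} "
                f"for depth_levels={self.depth_levels}"
            )

    def _forward_core(self, x: np.ndarray, *, train: bool):
        self._check_spatial(x)
        acts = self.activations if self._capture else None
        cap = self._capture
        skips = []
        h = np.asarray(x, dtype=np.float32)
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train=train, acts=acts, capture=cap)
            skips.append(h)
            h = pool.forward(h, train=train)
        h = self.bottleneck.forward(h, train=train, acts=acts, capture=cap)
        for i in reversed(range(self.depth_levels - 1)):
            h = self.upconvs[i].forward(h, train=train)
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec_blocks[i].forward(h, train=train, acts=acts, capture=cap)
        feats = h
        logits = self.out_conv.forward(h, train=train)
        if acts is not None and "out_conv" in cap:
            acts["out_conv"] = logits
        if train:
            self._cache["skip_channels"] = [s.shape[1] for s in skips]
        return logits, feats

    def forward_logits(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        logits, _ = self._forward_core(x, train=train)
        return logits

    def forward_features(self, x: np.ndarray, *, train: bool = False) -> np.ndarray:
        """Penultimate activations — the feature maps feeding the output layer."""
        _, feats = self._forward_core(x, train=train)
        return feats

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate from the output-layer logits; returns d(input).

        Must follow a ``train=True`` forward.  Parameter gradients
        accumulate in place; captured activation gradients land in
        ``captured_grads``.
        """
        grads = self.captured_grads if self._capture else None
        if grads is not None and "out_conv" in self._capture:
            grads["out_conv"] = dlogits
        g = self.out_conv.backward(dlogits)
        return self.backward_from_features(g)

    def backward_from_features(self, dfeats: np.ndarray) -> np.ndarray:
        """Backpropagate from the penultimate feature maps (skips the
        output layer) — used when the output layer has been stripped."""
        grads = self.captured_grads if self._capture else None
        cap = self._capture
        g = dfeats
        skip_grads: list[np.ndarray] = []
        for i in range(self.depth_levels - 1):
            g = self.dec_blocks[i].backward(g, grads=grads, capture=cap)
            n_skip = self._cache["skip_channels"][i]
            g_skip, g_up = g[:, :n_skip], g[:, n_skip:]
            skip_grads.append(np.ascontiguousarray(g_skip))
            g = self.upconvs[i].backward(np.ascontiguousarray(g_up))
        g = self.bottleneck.backward(g, grads=grads, capture=cap)
        for i in reversed(range(self.depth_levels - 1)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(g, grads=grads, capture=cap)
        return g
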