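"""Multiscale embedding-compression attention block (MECS).

Operates on rank-4 feature grids (batch, channels, height, width) and
applies, in order:

1. *Global perception* — a pointwise (1×1) convolution with GELU.
2. *Channel attention* — average, max and lower-median pooling over the
   spatial plane, each pooled descriptor passed through one shared
   Conv–ReLU–Conv pointwise MLP and a sigmoid; the three maps are summed,
   so every attention entry lies in (0, 3), and multiplied onto the grid
   channel-wise.
3. *Spatial attention* — a 5×5 depthwise convolution followed by three
   depthwise asymmetric branch pairs (1×7·7×1, 1×11·11×1, 1×21·21×1) whose
   outputs are summed.
4. *Fusion* — a pointwise convolution of the spatial map, elementwise
   multiplication with the channel-enhanced grid, and a final pointwise
   integration convolution.

Reduced 200-dimensional peptide features are adapted to grids of shape
(B, 8, 1, 25) before entering the block, keeping the long asymmetric
kernels meaningful along the feature axis.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Module, Tensor

#: Default grid adaptation for 200-dim reduced features.
GRID_CHANNELS = 8
GRID_WIDTH = 25

ASYMMETRIC_LENGTHS = (7, 11, 21)


class MECS(Module):
    """The full attention block; ``channels`` in == out by default."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction_ratio: int = 4):
        hidden = max(channels // reduction_ratio, 1)
        self.perception = Conv2d(channels, channels, (1, 1), rng)
        # shared channel MLP (two pointwise convs around a ReLU)
        self.mlp_in = Conv2d(channels, hidden, (1, 1), rng)
        self.mlp_out = Conv2d(hidden, channels, (1, 1), rng)
        self.depthwise5 = Conv2d(channels, channels, (5, 5), rng, groups=channels)
        self.branches = [
            (
                Conv2d(channels, channels, (1, k), rng, groups=channels),
                Conv2d(channels, channels, (k, 1), rng, groups=channels),
            )
            for k in ASYMMETRIC_LENGTHS
        ]
        self.spatial_proj = Conv2d(channels, channels, (1, 1), rng)   # W_p''
        self.output_proj = Conv2d(channels, channels, (1, 1), rng)    # W_p'

    # -- stages ----------------------------------------------------------
    def global_perception(self, x: Tensor) -> Tensor:
        return self.perception(x).gelu()

    def _channel_mlp(self, pooled: Tensor) -> Tensor:
        return self.mlp_out(self.mlp_in(pooled).relu()).sigmoid()

    def channel_attention(self, x_prime: Tensor) -> tuple[Tensor, Tensor]:
        """Return (attention map A_c in (0,3) per channel, weighted grid X_c)."""
        B, C, H, W = x_prime.shape
        flat = x_prime.reshape(B, C, 1, H * W)
        avg = flat.mean(axis=3, keepdims=True)
        mx = flat.max(axis=3, keepdims=True)
        med = flat.median_lower(axis=3, keepdims=True)
        a_c = self._channel_mlp(avg) + self._channel_mlp(mx) + self._channel_mlp(med)
        a_c = a_c.reshape(B, C, 1, 1)
        return a_c, a_c * x_prime

    def spatial_attention(self, x_c: Tensor) -> Tensor:
        base = self.depthwise5(x_c)
        out = None
        for conv_row, conv_col in self.branches:
            branch = conv_col(conv_row(base))
            out = branch if out is None else out + branch
        return out

    def __call__(self, x: Tensor) -> Tensor:
        x_prime = self.global_perception(x)
        _, x_c = self.channel_attention(x_prime)
        x_s = self.spatial_attention(x_c)
        return self.output_proj(self.spatial_proj(x_s) * x_c)


def to_grid(features: np.ndarray, channels: int = GRID_CHANNELS) -> np.ndarray:
    """Reshape (B, d) feature rows to (B, channels, 1, d // channels) grids."""
    features = np.atleast_2d(features)
    B, d = features.shape
    if d % channels:
        raise ValueError(f"feature dim {d} not divisible by {channels} channels")
    return features.reshape(B, channels, 1, d // channels)
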