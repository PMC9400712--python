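"""Self-attention operator and the self-attention fusion block (SA-FB).

The fusion strategy merges the two modalities' feature pyramids
hierarchically: at every level the two per-modality maps are concatenated
and passed through a self-attention operator that weights features by their
internal relevance (no hand-crafted selection such as taking extreme
values), then a 1x1 conv, concatenation with the running fusion state, and
a 3x3 conv.  Down-path blocks use batch-norm + leaky ReLU and end with a
max pool; up-path blocks keep batch-norm but use ReLU and no pool.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat
from . import nn

__all__ = ["SelfAttention", "SAFB"]


class SelfAttention(nn.Module):
    """Query/key/value self-attention with a learned residual gate.

    Query and key are 1x1 convs at ``channels / reduction`` width, value at
    full width; the attention matrix is a row-softmax over key positions and
    the output is ``gamma * (attention-weighted value) + input`` with the
    scalar gate ``gamma`` initialized to 0, so a fresh block is the identity.
    """

    def __init__(self, channels: int, reduction: int = 8, *, rng):
        super().__init__()
        if channels < reduction:
            raise ValueError(f"need at least {reduction} channels, got {channels}")
        inner = max(1, channels // reduction)
        self.query = nn.Conv2d(channels, inner, 1, rng=rng)
        self.key = nn.Conv2d(channels, inner, 1, rng=rng)
        self.value = nn.Conv2d(channels, channels, 1, rng=rng)
        self.gamma = nn.Parameter(np.zeros(1, dtype=np.float32))
        self.channels = channels

    def _attention(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        n = H * W
        q = self.query(x).reshape(B, -1, n).transpose(0, 2, 1)  # (B, N, C')
        k = self.key(x).reshape(B, -1, n)  # (B, C', N)
        return (q @ k).softmax(axis=-1)  # rows sum to 1

    def attention_map(self, x) -> np.ndarray:
        """Row-stochastic (H*W) x (H*W) attention weights (inspection helper)."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        return self._attention(x).data

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        n = H * W
        attn = self._attention(x)  # (B, N, N)
        v = self.value(x).reshape(B, C, n).transpose(0, 2, 1)  # (B, N, C)
        out = (attn @ v).transpose(0, 2, 1).reshape(B, C, H, W)
        return self.gamma.reshape(1, 1, 1, 1) * out + x


class SAFB(nn.Module):
    """One self-attention fusion block.

    Inputs are the two modality features of one pyramid level (``channels``
    each) and the running fusion state (``fsa_channels``; 0 for the very
    first block, whose fusion input is null).  ``down=True`` selects the
    down-path variant (leaky ReLU + trailing max pool); otherwise the block
    uses ReLU and keeps the spatial size.  ``use_sa=False`` bypasses the
    attention operator — with a freshly initialized gate the two variants
    coincide numerically.
    """

    def __init__(
        self,
        channels: int,
        fsa_channels: int,
        out_channels: int,
        *,
        down: bool,
        use_sa: bool = True,
        reduction: int = 8,
        slope: float = 0.2,
        rng,
    ):
        super().__init__()
        cc = 2 * channels
        self.use_sa = use_sa
        if use_sa:
            self.sa = SelfAttention(cc, reduction, rng=rng)
        self.conv1 = nn.Conv2d(cc, cc, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(cc)
        self.conv2 = nn.Conv2d(cc + fsa_channels, out_channels, 3, 1, 1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)
        self.down = down
        self.slope = slope
        self.fsa_channels = fsa_channels

    def _act(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope) if self.down else x.relu()

    def forward(self, f1: Tensor, f2: Tensor, f_sa: Tensor | None) -> Tensor:
        if f1.shape != f2.shape:
            raise ValueError(f"modality feature shapes differ: {f1.shape} vs {f2.shape}")
        if (f_sa is None) != (self.fsa_channels == 0):
            raise ValueError("fusion-state input does not match block wiring")
        x = concat([f1, f2], axis=1)
        if self.use_sa:
            x = self.sa(x)
        x = self._act(self.bn1(self.conv1(x)))
        if f_sa is not None:
            if f_sa.shape[-1] != x.shape[-1]:
                raise ValueError(
                    f"fusion state side {f_sa.shape[-1]} != level side {x.shape[-1]}"
                )
            x = concat([x, f_sa], axis=1)
        x = self._act(self.bn2(self.conv2(x)))
        if self.down:
            x = nn.maxpool2x2(x)
        return x
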