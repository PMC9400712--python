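"""MOS conditioning, the per-modality encoder, the decoder, and L_ED.

Each source modality image is concatenated with a constant plane holding the
fused image's mean opinion score, then passed through a three-block
convolutional encoder.  Every block is two (conv 3x3 / stride 1 / pad 1 ->
batch-norm -> leaky ReLU) stages followed by a 2x2 max pool, so block j
emits a feature map of side ``input_side / 2**j`` — the three maps form the
feature pyramid consumed by the fusion blocks.  A seven-group transposed-
convolution decoder reconstructs the modality image from the deepest map
alone (no skip connections); the summed absolute reconstruction error over
both modalities is the encoder-decoder loss L_ED.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat
from . import nn

__all__ = ["condition", "Encoder", "Decoder", "loss_ed"]


def condition(img: np.ndarray, mos: float) -> np.ndarray:
    """Stack a gray image with a constant MOS plane -> (2, H, W) array."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("condition expects a 2-D gray image")
    if not 0.0 <= mos <= 1.0:
        raise ValueError(f"mos={mos} outside [0, 1]")
    return np.stack([img, np.full_like(img, mos)], axis=0)


class _ConvBNAct(nn.Module):
    def __init__(self, cin, cout, k, stride, padding, *, rng, act="lrelu", slope=0.2):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride, padding, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act, self.slope = act, slope

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.act == "relu" else x.leaky_relu(self.slope)


class Encoder(nn.Module):
    """Three conv blocks, each two conv/BN/leaky-ReLU stages plus a max pool."""

    def __init__(self, widths=(32, 64, 128), in_channels=2, *, rng, slope=0.2):
        super().__init__()
        if len(widths) != 3:
            raise ValueError("encoder needs exactly three block widths")
        cin = in_channels
        blocks = []
        for w in widths:
            blocks.append(_ConvBNAct(cin, w, 3, 1, 1, rng=rng, slope=slope))
            blocks.append(_ConvBNAct(w, w, 3, 1, 1, rng=rng, slope=slope))
            cin = w
        self.stages = nn.ModuleList(blocks)
        self.widths = tuple(widths)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the three pooled feature maps (sides S/2, S/4, S/8)."""
        side = x.shape[-1]
        if side % 8 != 0:
            raise ValueError(f"input side {side} not divisible by 8")
        pyramid = []
        for j in range(3):
            x = self.stages[2 * j](x)
            x = self.stages[2 * j + 1](x)
            x = nn.maxpool2x2(x)
            pyramid.append(x)
        return pyramid


class Decoder(nn.Module):
    """Seven transposed-conv groups mapping the deepest map back to image size.

    Bridging side/8 -> side requires exactly three 2x up-samplings; the
    remaining four groups are stride-1 refiners, interleaved
    (s1, s2, s1, s2, s1, s2, s1).  Each group is deconv -> BN -> ReLU; a
    final linear 3x3 conv produces ``out_channels`` planes clipped to [0,1].
    """

    def __init__(self, widths=(32, 64, 128), image_side=128, out_channels=1, *, rng):
        super().__init__()
        w1, w2, w3 = widths
        plan = [  # (stride, cin, cout)
            (1, w3, w3),
            (2, w3, w2),
            (1, w2, w2),
            (2, w2, w1),
            (1, w1, w1),
            (2, w1, w1),
            (1, w1, w1),
        ]
        groups = []
        for s, cin, cout in plan:
            k = 4 if s == 2 else 3
            groups.append(_DeconvBNReLU(cin, cout, k, s, 1, rng=rng))
        self.groups = nn.ModuleList(groups)
        self.out = nn.Conv2d(w1, out_channels, 3, 1, 1, rng=rng, bias_init=0.5)
        self.image_side = image_side

    def forward(self, top: Tensor) -> Tensor:
        if top.shape[-1] != self.image_side // 8:
            raise ValueError(
                f"decoder expects side {self.image_side // 8}, got {top.shape[-1]}"
            )
        x = top
        for g in self.groups:
            x = g(x)
        return self.out(x).clip(0.0, 1.0)


class _DeconvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, stride, padding, *, rng):
        super().__init__()
        self.deconv = nn.ConvTranspose2d(cin, cout, k, stride, padding, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.deconv(x)).relu()


def loss_ed(mi_pairs) -> Tensor:
    """Sum of absolute reconstruction differences over both modalities.

    ``mi_pairs`` is a list of (original, reconstruction) for each modality;
    the result is the raw (unnormalized) sum of |MI_i - MI_i_hat| over all
    pixels of all pairs.
    """
    total = None
    for orig, recon in mi_pairs:
        orig_t = orig if isinstance(orig, Tensor) else Tensor(np.asarray(orig))
        recon_t = recon if isinstance(recon, Tensor) else Tensor(np.asarray(recon))
        if orig_t.shape != recon_t.shape:
            raise ValueError(f"shape mismatch: {orig_t.shape} vs {recon_t.shape}")
        term = (orig_t - recon_t).abs().sum()
        total = term if total is None else total + term
    if total is None:
        raise ValueError("loss_ed needs at least one (image, reconstruction) pair")
    return total
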