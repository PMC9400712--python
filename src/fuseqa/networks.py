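"""Generator and discriminator assembly plus the adversarial losses.

The generator conditions both source-modality images on a target MOS,
encodes them with the dual-channel encoders, fuses the feature pyramids
through the hierarchical self-attention fusion blocks (three pooled
down-path blocks, then three up-path blocks that re-consume the pyramid
features while the fusion state is nearest-neighbour up-sampled between
levels), and emits the fused image through a linear 3x3 conv clipped to
[0, 1].  Early- and late-fusion ablation wirings are built by the same
factory.

The discriminator conditions the candidate fused image on the same MOS
plane, halves the side through four discriminator blocks (conv 3x3 / s2 /
p1 -> BN -> leaky ReLU) and applies a final unpadded 3x3 conv, giving a
6x6 score map for 128-side inputs.  The adversarial objective is
least-squares (targets 1 for real, 0 for fake); the log-form objective is
available behind ``adversarial_form="log"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, concat, no_grad
from . import nn
from .attention import SAFB
from .config import RunConfig
from .encoder_decoder import Decoder, Encoder, _ConvBNAct

__all__ = [
    "Generator",
    "Discriminator",
    "GeneratorOutput",
    "build_generator",
    "build_discriminator",
    "generate",
    "discriminate",
    "loss_fusion",
    "loss_G",
    "loss_D",
    "score_map_side",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _with_mos_plane(images: np.ndarray | Tensor, mos: np.ndarray) -> Tensor:
    """(B, C, S, S) batch -> (B, C+1, S, S) with a constant per-sample MOS plane."""
    t = _as_tensor(images)
    B, _, H, W = t.shape
    mos = np.asarray(mos, dtype=np.float32).reshape(B, 1, 1, 1)
    if np.any((mos < 0) | (mos > 1)):
        raise ValueError("mos values must lie in [0, 1]")
    plane = Tensor(np.broadcast_to(mos, (B, 1, H, W)).copy())
    return concat([t, plane], axis=1)


@dataclass
class GeneratorOutput:
    fused: np.ndarray
    ssim_ready: bool = True
    intermediate: list | None = None


class Generator(nn.Module):
    """Conditional fusion generator (hierarchical, early, or late wiring)."""

    def __init__(self, config: RunConfig, *, rng):
        super().__init__()
        w1, w2, w3 = config.channel_widths
        mode, use_sa = config.fusion_mode, config.use_sa
        red, slope = config.attention_reduction, config.leaky_slope
        self.mode, self.use_sa = mode, use_sa
        self.image_side = config.image_side

        if mode == "hierarchical":
            self.encoder1 = Encoder((w1, w2, w3), 2, rng=rng, slope=slope)
            self.encoder2 = Encoder((w1, w2, w3), 2, rng=rng, slope=slope)
            self.decoder1 = Decoder((w1, w2, w3), config.image_side, 1, rng=rng)
            self.decoder2 = Decoder((w1, w2, w3), config.image_side, 1, rng=rng)
            self.down_blocks = nn.ModuleList(
                [
                    SAFB(w1, 0, w1, down=True, use_sa=use_sa, reduction=red, slope=slope, rng=rng),
                    SAFB(w2, w1, w2, down=True, use_sa=use_sa, reduction=red, slope=slope, rng=rng),
                    SAFB(w3, w2, w3, down=True, use_sa=use_sa, reduction=red, slope=slope, rng=rng),
                ]
            )
            self.up_blocks = nn.ModuleList(
                [
                    SAFB(w3, w3, w3, down=False, use_sa=use_sa, reduction=red, slope=slope, rng=rng),
                    SAFB(w2, w3, w2, down=False, use_sa=use_sa, reduction=red, slope=slope, rng=rng),
                    SAFB(w1, w2, w1, down=False, use_sa=use_sa, reduction=red, slope=slope, rng=rng),
                ]
            )
            self.head = nn.Conv2d(w1, 1, 3, 1, 1, rng=rng, bias_init=0.5)
        elif mode == "early":
            # one shared encoder on the 3-channel concatenation (MI1, MI2, MOS)
            self.encoder = Encoder((w1, w2, w3), 3, rng=rng, slope=slope)
            self.decoder = Decoder((w1, w2, w3), config.image_side, 2, rng=rng)
            self._build_upsample_head(w1, w2, w3, rng)
        elif mode == "late":
            # dual encoders; a single fusion of the deepest (level-3) features
            self.encoder1 = Encoder((w1, w2, w3), 2, rng=rng, slope=slope)
            self.encoder2 = Encoder((w1, w2, w3), 2, rng=rng, slope=slope)
            self.decoder1 = Decoder((w1, w2, w3), config.image_side, 1, rng=rng)
            self.decoder2 = Decoder((w1, w2, w3), config.image_side, 1, rng=rng)
            self.fuse_block = SAFB(
                w3, 0, w3, down=False, use_sa=use_sa, reduction=red, slope=slope, rng=rng
            )
            self._build_upsample_head(w1, w2, w3, rng)
        else:  # pragma: no cover - RunConfig validates
            raise ValueError(f"unknown fusion mode {mode!r}")

    def _build_upsample_head(self, w1, w2, w3, rng):
        self.up_convs = nn.ModuleList(
            [
                _ConvBNAct(w3, w3, 3, 1, 1, rng=rng, act="relu"),
                _ConvBNAct(w3, w2, 3, 1, 1, rng=rng, act="relu"),
                _ConvBNAct(w2, w1, 3, 1, 1, rng=rng, act="relu"),
            ]
        )
        self.head = nn.Conv2d(w1, 1, 3, 1, 1, rng=rng, bias_init=0.5)

    # ------------------------------------------------------------------ fwd
    def forward(self, mi1: np.ndarray, mi2: np.ndarray, mos: np.ndarray) -> dict:
        """Run a batch: mi1/mi2 are (B, S, S) in [0,1], mos is (B,).

        Returns ``{"fused": Tensor (B,1,S,S), "recon_pairs": [(orig, recon), ...]}``
        where recon_pairs feed the encoder-decoder reconstruction loss.
        """
        mi1 = np.asarray(mi1, dtype=np.float32)
        mi2 = np.asarray(mi2, dtype=np.float32)
        if mi1.shape != mi2.shape:
            raise ValueError(f"modality batch shapes differ: {mi1.shape} vs {mi2.shape}")
        if mi1.shape[-1] != self.image_side:
            raise ValueError(
                f"generator built for side {self.image_side}, got {mi1.shape[-1]}"
            )
        b1 = mi1[:, None, :, :]
        b2 = mi2[:, None, :, :]
        if self.mode == "early":
            x = _with_mos_plane(np.concatenate([b1, b2], axis=1), mos)
            pyr = self.encoder(x)
            recon = self.decoder(pyr[2])  # 2 channels: both modalities
            pairs = [
                (Tensor(b1), _slice_channel(recon, 0)),
                (Tensor(b2), _slice_channel(recon, 1)),
            ]
            u = pyr[2]
        else:
            x1 = _with_mos_plane(b1, mos)
            x2 = _with_mos_plane(b2, mos)
            p1 = self.encoder1(x1)
            p2 = self.encoder2(x2)
            pairs = [
                (Tensor(b1), self.decoder1(p1[2])),
                (Tensor(b2), self.decoder2(p2[2])),
            ]
            if self.mode == "late":
                u = self.fuse_block(p1[2], p2[2], None)
            else:
                f_sa = self.down_blocks[0](p1[0], p2[0], None)
                f_sa = self.down_blocks[1](p1[1], p2[1], f_sa)
                f_sa = self.down_blocks[2](p1[2], p2[2], f_sa)
                u = nn.upsample_nearest2x(f_sa)  # S/8
                u = self.up_blocks[0](p1[2], p2[2], u)
                u = nn.upsample_nearest2x(u)  # S/4
                u = self.up_blocks[1](p1[1], p2[1], u)
                u = nn.upsample_nearest2x(u)  # S/2
                u = self.up_blocks[2](p1[0], p2[0], u)
                u = nn.upsample_nearest2x(u)  # S
                fused = self.head(u).clip(0.0, 1.0)
                return {"fused": fused, "recon_pairs": pairs}
        # early/late shared up-sampling head from S/8 features
        for conv in self.up_convs:
            u = nn.upsample_nearest2x(conv(u))
        fused = self.head(u).clip(0.0, 1.0)
        return {"fused": fused, "recon_pairs": pairs}


def _slice_channel(x: Tensor, c: int) -> Tensor:
    data = x.data[:, c : c + 1]
    out = Tensor(data)
    if x.requires_grad:

        def backward(g):
            full = np.zeros_like(x.data)
            full[:, c : c + 1] = g
            x._accum(full)

        out.requires_grad = True
        out._prev = (x,)
        out._backward = backward
    return out


def score_map_side(image_side: int) -> int:
    """Discriminator score-map side: four halvings then an unpadded 3x3 conv."""
    s = image_side
    for _ in range(4):
        s //= 2
    return s - 2


class Discriminator(nn.Module):
    """Four stride-2 discriminator blocks plus a final unpadded 3x3 conv."""

    def __init__(self, config: RunConfig, *, rng):
        super().__init__()
        side = config.image_side
        if side % 16 != 0 or side < 48:
            raise ValueError("discriminator requires image_side divisible by 16 and >= 48")
        widths = config.disc_widths
        cin = 2  # candidate image + MOS plane
        blocks = []
        for w in widths:
            blocks.append(_ConvBNAct(cin, w, 3, 2, 1, rng=rng, slope=config.leaky_slope))
            cin = w
        self.blocks = nn.ModuleList(blocks)
        self.final = nn.Conv2d(cin, 1, 3, 1, 0, rng=rng)
        self.image_side = side

    def forward(self, candidate, mos: np.ndarray) -> Tensor:
        x = _as_tensor(candidate)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("discriminator expects a (B, 1, S, S) batch")
        if x.shape[-1] != self.image_side:
            raise ValueError(
                f"discriminator built for side {self.image_side}, got {x.shape[-1]}"
            )
        x = _with_mos_plane(x, mos)
        for b in self.blocks:
            x = b(x)
        return self.final(x)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def loss_fusion(y_true, y_hat) -> Tensor:
    """Mean absolute pixel difference between true and generated fused images."""
    a, b = _as_tensor(y_true), _as_tensor(y_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return (a - b).abs().mean()


def loss_G(fake_scores, l_fusion, alpha: float, form: str = "lsgan") -> Tensor:
    """Generator objective: adversarial term plus alpha * L_fusion."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    s = _as_tensor(fake_scores)
    lf = l_fusion if isinstance(l_fusion, Tensor) else Tensor(np.float32(l_fusion))
    if form == "lsgan":
        adv = ((s - 1.0) ** 2).mean()
    elif form == "log":
        adv = ((1.0 - s.sigmoid() + 1e-8).log()).mean()
    else:
        raise ValueError(f"unknown adversarial form {form!r}")
    return adv + alpha * lf


def loss_D(real_scores, fake_scores, form: str = "lsgan") -> Tensor:
    """Discriminator objective (real target 1, fake target 0), halved."""
    r, f = _as_tensor(real_scores), _as_tensor(fake_scores)
    if r.shape != f.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {f.shape}")
    if form == "lsgan":
        return (((r - 1.0) ** 2).mean() + (f**2).mean()) / 2.0
    if form == "log":
        return -(
            ((r.sigmoid() + 1e-8).log()).mean() + ((1.0 - f.sigmoid() + 1e-8).log()).mean()
        )
    raise ValueError(f"unknown adversarial form {form!r}")


# --------------------------------------------------------------------------
# factory / single-image front doors
# --------------------------------------------------------------------------

def build_generator(config: RunConfig, rng=None) -> Generator:
    rng = np.random.default_rng(config.seed) if rng is None else rng
    return Generator(config, rng=rng)


def build_discriminator(config: RunConfig, rng=None) -> Discriminator:
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    return Discriminator(config, rng=rng)


def generate(mi1: np.ndarray, mi2: np.ndarray, mos: float, state) -> GeneratorOutput:
    """Generate one fused image at the given MOS condition (inference mode)."""
    if not 0.0 <= mos <= 1.0:
        raise ValueError("mos must lie in [0, 1]")
    gen = state.generator
    was_training = gen.training
    gen.eval()
    try:
        with no_grad():
            out = gen.forward(mi1[None], mi2[None], np.array([mos]))
    finally:
        gen.train(was_training)
    return GeneratorOutput(fused=np.asarray(out["fused"].data[0, 0], dtype=np.float64))


def discriminate(candidate: np.ndarray, mos: float, state) -> np.ndarray:
    """Score one candidate fused image; returns the 2-D score map."""
    disc = state.discriminator
    was_training = disc.training
    disc.eval()
    try:
        with no_grad():
            scores = disc.forward(candidate[None, None], np.array([mos]))
    finally:
        disc.train(was_training)
    return np.asarray(scores.data[0, 0], dtype=np.float64)
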