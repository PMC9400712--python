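"""Alternating adversarial training of the fusion-quality model.

Each step first updates the discriminator on true fused images versus
generated ones (generator detached), then updates the generator together
with the encoder-decoders on the combined objective

    loss_G(adversarial + alpha * L_fusion)  +  beta * L_ED_norm

where L_ED_norm is the Eq.-style summed absolute reconstruction error
normalized per pixel, so the default beta = 20 is stable across image
sides.  The model is evaluated on a held-out validation split at the end
of every epoch and the checkpoint with the best validation SRCC is kept.
"""

from __future__ import annotations


import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import no_grad
from . import nn
from .config import RunConfig
from .encoder_decoder import loss_ed
from .io import Manifest, load_image, resize
from .networks import (
    Discriminator,
    Generator,
    build_discriminator,
    build_generator,
    loss_D,
    loss_fusion,
    loss_G,
)

log = logging.getLogger("fuseqa")

CHECKPOINT_MAGIC = "FUSEQA-CKPT-1"


@dataclass
class FusionSample:
    """One training unit: two source images, the fused image, and its MOS."""

    mi1: np.ndarray
    mi2: np.ndarray
    y_true: np.ndarray
    mos: float
    pair_key: tuple = ()


@dataclass
class ModelState:
    generator: Generator
    discriminator: Discriminator
    config: RunConfig
    epoch: int = 0
    best_epoch: int = -1
    best_srcc: float = float("-inf")
    g_opt: nn.Adam | None = None
    d_opt: nn.Adam | None = None


def init_state(config: RunConfig) -> ModelState:
    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, rng)
    disc = build_discriminator(config, rng)
    state = ModelState(generator=gen, discriminator=disc, config=config)
    state.g_opt = nn.Adam(gen.parameters(), lr=config.learning_rate)
    state.d_opt = nn.Adam(disc.parameters(), lr=config.learning_rate)
    return state


def build_ablation(config: RunConfig) -> Generator:
    """Build the generator wiring for the configured fusion mode / SA switch."""
    return build_generator(config)


# --------------------------------------------------------------------------
# data handling
# --------------------------------------------------------------------------

def load_samples(manifest: Manifest, image_side: int) -> list[FusionSample]:
    cache: dict = {}
    samples = []
    for rec in manifest:
        key = (rec.mi1, rec.mi2)
        if key not in cache:
            cache[key] = (
                resize(load_image(rec.mi1), image_side),
                resize(load_image(rec.mi2), image_side),
            )
        mi1, mi2 = cache[key]
        samples.append(
            FusionSample(
                mi1=mi1,
                mi2=mi2,
                y_true=resize(load_image(rec.fused), image_side),
                mos=rec.mos,
                pair_key=key,
            )
        )
    return samples


def split_by_pair(samples: list[FusionSample], val_fraction: float, seed: int):
    """Deterministic 80/20-style split keeping all fusions of a pair together."""
    pairs = sorted({s.pair_key for s in samples})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs))))
    if n_val >= len(pairs):
        raise ValueError("not enough pairs to carve a validation split")
    val_pairs = {pairs[i] for i in order[:n_val]}
    train = [s for s in samples if s.pair_key not in val_pairs]
    val = [s for s in samples if s.pair_key in val_pairs]
    return train, val


def _batch_arrays(batch: list[FusionSample]):
    mi1 = np.stack([s.mi1 for s in batch]).astype(np.float32)
    mi2 = np.stack([s.mi2 for s in batch]).astype(np.float32)
    y = np.stack([s.y_true for s in batch]).astype(np.float32)[:, None]
    mos = np.array([s.mos for s in batch], dtype=np.float32)
    return mi1, mi2, y, mos


# --------------------------------------------------------------------------
# optimisation
# --------------------------------------------------------------------------

def _check_finite(value: float, term: str) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss in term {term!r}: {value}")
    return value


def train_step(batch: list[FusionSample], state: ModelState) -> dict[str, float]:
    """One discriminator update then one generator update on the batch.

    Returns the step's loss values: ``loss_D``, ``loss_G`` (adversarial +
    alpha * L_fusion), ``loss_ED`` (per-pixel normalized reconstruction
    error) and ``loss_fusion``.
    """
    if not batch:
        raise ValueError("batch must be nonempty")
    cfg = state.config
    mi1, mi2, y, mos = _batch_arrays(batch)

    # ---- discriminator step (generator detached via no-grad forward)
    with no_grad():
        fake = state.generator.forward(mi1, mi2, mos)["fused"].detach()
    real_scores = state.discriminator.forward(y, mos)
    fake_scores = state.discriminator.forward(fake, mos)
    d_loss = loss_D(real_scores, fake_scores, cfg.adversarial_form)
    state.d_opt.zero_grad()
    d_loss.backward()
    state.d_opt.step()

    # ---- generator + encoder-decoder step
    out = state.generator.forward(mi1, mi2, mos)
    fake_scores_g = state.discriminator.forward(out["fused"], mos)
    l_fus = loss_fusion(y, out["fused"])
    g_loss = loss_G(fake_scores_g, l_fus, cfg.alpha, cfg.adversarial_form)
    l_ed_raw = loss_ed(out["recon_pairs"])
    n_elem = sum(orig.data.size for orig, _ in out["recon_pairs"])
    l_ed_norm = l_ed_raw / float(n_elem)
    total = g_loss + cfg.beta * l_ed_norm
    state.g_opt.zero_grad()
    total.backward()
    state.g_opt.step()

    return {
        "loss_D": _check_finite(d_loss.item(), "loss_D"),
        "loss_G": _check_finite(g_loss.item(), "loss_G"),
        "loss_ED": _check_finite(l_ed_norm.item(), "loss_ED"),
        "loss_fusion": _check_finite(l_fus.item(), "loss_fusion"),
    }


def train(manifest: Manifest, config: RunConfig) -> tuple[ModelState, pd.DataFrame]:
    """Full training run; returns the best-SRCC checkpoint and the history.

    The manifest is split 80/20 by source pair (all five fusions of a pair
    stay on one side).  After every epoch the validation fusions are scored
    through the five-condition quality scorer and SRCC/KRCC/PLCC/RMSE
    against their MOS labels are recorded; the returned model carries the
    parameters of the epoch with the highest validation SRCC.
    """
    from .quality import agreement, score_quality  # deferred: avoids cycle

    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    samples = load_samples(manifest, config.image_side)
    train_set, val_set = split_by_pair(samples, config.val_fraction, config.seed)
    log.info("training on %d samples, validating on %d", len(train_set), len(val_set))

    state = init_state(config)
    shuffle_rng = np.random.default_rng(config.seed + 10_000)
    history: list[dict] = []
    best_params: dict | None = None

    for epoch in range(config.epochs):
        state.generator.train()
        state.discriminator.train()
        order = shuffle_rng.permutation(len(train_set))
        epoch_losses: list[dict] = []
        for start in range(0, len(train_set), config.batch_size):
            batch = [train_set[i] for i in order[start : start + config.batch_size]]
            epoch_losses.append(train_step(batch, state))
        means = {k: float(np.mean([e[k] for e in epoch_losses])) for k in epoch_losses[0]}

        preds = [score_quality(s.mi1, s.mi2, s.y_true, state).q for s in val_set]
        labels = [s.mos for s in val_set]
        rep = agreement(preds, labels)
        # undefined correlations (constant predictions) enter the history as 0
        val_srcc = rep.srcc if np.isfinite(rep.srcc) else 0.0
        record = {
            "epoch": epoch,
            **means,
            "val_srcc": val_srcc,
            "val_krcc": rep.krcc if np.isfinite(rep.krcc) else 0.0,
            "val_plcc": rep.plcc if np.isfinite(rep.plcc) else 0.0,
            "val_rmse": rep.rmse,
        }
        history.append(record)
        state.epoch = epoch + 1
        if val_srcc > state.best_srcc:
            state.best_srcc = val_srcc
            state.best_epoch = epoch
            best_params = {
                "g": state.generator.state_dict(),
                "d": state.discriminator.state_dict(),
            }
        log.info(
            "epoch %d: loss_G=%.4f loss_D=%.4f loss_ED=%.4f val_srcc=%.4f",
            epoch, means["loss_G"], means["loss_D"], means["loss_ED"], val_srcc,
        )

    if best_params is not None:
        state.generator.load_state_dict(best_params["g"])
        state.discriminator.load_state_dict(best_params["d"])
    return state, pd.DataFrame(history)


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path) -> None:
    """Serialize all parameters, buffers and config to a single .npz bundle."""
    arrays = {f"g.{k}": v for k, v in state.generator.state_dict().items()}
    arrays.update({f"d.{k}": v for k, v in state.discriminator.state_dict().items()})
    meta = {
        "magic": CHECKPOINT_MAGIC,
        "config": state.config.to_dict(),
        "epoch": state.epoch,
        "best_epoch": state.best_epoch,
        "best_srcc": None if not np.isfinite(state.best_srcc) else state.best_srcc,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_checkpoint(path) -> ModelState:
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
        if meta.get("magic") != CHECKPOINT_MAGIC:
            raise ValueError(f"{path} is not a fuseqa checkpoint")
        config = RunConfig.from_dict(meta["config"])
        state = init_state(config)
        state.generator.load_state_dict(
            {k[2:]: data[k] for k in data.files if k.startswith("g.")}
        )
        state.discriminator.load_state_dict(
            {k[2:]: data[k] for k in data.files if k.startswith("d.")}
        )
        state.epoch = int(meta["epoch"])
        state.best_epoch = int(meta["best_epoch"])
        state.best_srcc = float("-inf") if meta["best_srcc"] is None else float(meta["best_srcc"])
    return state
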