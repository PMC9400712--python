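"""Run configuration: network widths, loss weights, training schedule."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

FUSION_MODES = ("hierarchical", "early", "late")
ADVERSARIAL_FORMS = ("lsgan", "log")


@dataclass
class RunConfig:
    """Everything the model build and the training loop depend on.

    alpha weights the L1 fusion term inside the generator objective
    (default 100); beta weights the encoder-decoder reconstruction term in
    the total objective (default 20).  fusion_mode selects the full
    hierarchical self-attention fusion or the early/late-fusion ablations;
    use_sa=False bypasses the self-attention operator inside the fusion
    blocks.
    """

    image_side: int = 128
    channel_widths: tuple[int, int, int] = (32, 64, 128)
    disc_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    alpha: float = 100.0
    beta: float = 20.0
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 2e-4
    seed: int = 0
    fusion_mode: str = "hierarchical"
    use_sa: bool = True
    adversarial_form: str = "lsgan"
    val_fraction: float = 0.2
    attention_reduction: int = 8
    leaky_slope: float = 0.2

    def __post_init__(self):
        self.channel_widths = tuple(int(w) for w in self.channel_widths)
        self.disc_widths = tuple(int(w) for w in self.disc_widths)
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.image_side % 8 != 0:
            raise ValueError("image_side must be divisible by 8")
        if len(self.channel_widths) != 3:
            raise ValueError("channel_widths must have exactly 3 entries")
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {FUSION_MODES}")
        if self.adversarial_form not in ADVERSARIAL_FORMS:
            raise ValueError(f"adversarial_form must be one of {ADVERSARIAL_FORMS}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_widths"] = list(self.channel_widths)
        d["disc_widths"] = list(self.disc_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
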