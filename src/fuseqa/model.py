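"""Model/Results front door.

``FusionQualityModel`` holds the data (a manifest of scored fusion
samples) and the run configuration; ``fit()`` runs the adversarial
training and returns a ``FusionQualityResults`` carrying the selected
checkpoint, the per-epoch history, and the scoring/evaluation methods.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import Manifest, load_image, load_manifest
from . import quality, training

__all__ = ["FusionQualityModel", "FusionQualityResults"]


class FusionQualityModel:
    """Conditional-GAN quality model for multimodal fusion images."""

    def __init__(self, manifest: Manifest, config: RunConfig | None = None):
        if not isinstance(manifest, Manifest):
            raise TypeError("manifest must be a fuseqa.io.Manifest")
        self.manifest = manifest
        self.config = config or RunConfig()

    @classmethod
    def from_manifest(cls, path, **config_overrides) -> "FusionQualityModel":
        """Build from a manifest CSV; keyword arguments override RunConfig fields."""
        return cls(load_manifest(path), RunConfig(**config_overrides))

    def fit(self) -> "FusionQualityResults":
        state, history = training.train(self.manifest, self.config)
        return FusionQualityResults(state, history)


class FusionQualityResults:
    """A fitted quality model: best checkpoint plus training history."""

    def __init__(self, state: training.ModelState, history: pd.DataFrame | None = None):
        self.state = state
        self.history = history if history is not None else pd.DataFrame()

    # ------------------------------------------------------------- scoring
    def score(self, mi1, mi2, fused) -> quality.QualityResult:
        """Score one fused image; arguments are arrays or image paths."""
        imgs = [
            load_image(x) if isinstance(x, (str, Path)) else np.asarray(x, dtype=np.float64)
            for x in (mi1, mi2, fused)
        ]
        return quality.score_quality(*imgs, self.state)

    def evaluate(self, manifest: Manifest | str | Path) -> quality.AgreementReport:
        if isinstance(manifest, (str, Path)):
            manifest = load_manifest(manifest)
        return quality.evaluate(manifest, self.state)

    # ------------------------------------------------------------ summary
    def summary(self) -> str:
        cfg = self.state.config
        lines = [
            "Fusion quality assessment (conditional GAN)",
            "=" * 47,
            f"fusion mode:        {cfg.fusion_mode} (self-attention: {cfg.use_sa})",
            f"image side:         {cfg.image_side}",
            f"channel widths:     {cfg.channel_widths}",
            f"alpha / beta:       {cfg.alpha:g} / {cfg.beta:g}",
            f"epochs trained:     {self.state.epoch}",
            f"best epoch (SRCC):  {self.state.best_epoch}",
        ]
        if not self.history.empty:
            best = self.history.iloc[self.history["val_srcc"].idxmax()]
            lines += [
                "-" * 47,
                "validation metrics at the selected checkpoint:",
                f"  SRCC = {best['val_srcc']:.4f}   KRCC = {best['val_krcc']:.4f}",
                f"  PLCC = {best['val_plcc']:.4f}   RMSE = {best['val_rmse']:.4f}",
            ]
        return "\n".join(lines)

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        training.save_checkpoint(self.state, path)
        if not self.history.empty:
            self.history.to_csv(Path(path).with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path) -> "FusionQualityResults":
        state = training.load_checkpoint(path)
        hist_path = Path(path).with_suffix(".history.csv")
        history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
        return cls(state, history)
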