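"""Quality scoring and agreement metrics.

A fused image is scored by generating five candidate fusions, one per MOS
condition on the grid {0.2, 0.4, 0.6, 0.8, 1.0}, and returning the
condition whose generated image is most SSIM-similar to the image under
test.  Agreement between predicted scores and reference MOS labels is
summarized by Spearman (SRCC), Kendall tau-b (KRCC) and Pearson (PLCC)
correlations plus RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from ._autograd import no_grad
from .io import Manifest, load_image, resize

log = logging.getLogger("fuseqa")

MOS_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity with the original 11x11 Gaussian window.

    sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1; mean over windows.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError("images must be at least 11 pixels on a side")
    return float(
        structural_similarity(
            a,
            b,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


@dataclass(frozen=True)
class QualityResult:
    """Per-condition SSIM values and the selected quality score."""

    ssim_by_k: tuple[float, float, float, float, float]
    q: float
    argmax_k: int  # 1-based index into the MOS grid

    def __post_init__(self):
        assert abs(self.q - 0.2 * self.argmax_k) < 1e-12


@dataclass(frozen=True)
class AgreementReport:
    srcc: float
    krcc: float
    plcc: float
    rmse: float
    n: int


def score_quality(fi1, fi2, fi12, state) -> QualityResult:
    """Score a fused image against its two source images.

    Generates the five MOS-conditioned fusions in one batch, computes the
    SSIM of each against the image under test, and returns the MOS of the
    best match; ties break toward the smallest condition.
    """
    side = state.config.image_side
    imgs = []
    for name, img in (("fi1", fi1), ("fi2", fi2), ("fi12", fi12)):
        img = np.asarray(img, dtype=np.float64)
        if img.shape != (side, side):
            log.warning("auto-resizing %s from %s to %dx%d", name, img.shape, side, side)
            img = resize(img, side)
        imgs.append(img)
    fi1, fi2, fi12 = imgs

    gen = state.generator
    was_training = gen.training
    gen.eval()
    try:
        with no_grad():
            mos = np.asarray(MOS_GRID)
            out = gen.forward(
                np.repeat(fi1[None], 5, axis=0), np.repeat(fi2[None], 5, axis=0), mos
            )
    finally:
        gen.train(was_training)
    fakes = np.asarray(out["fused"].data[:, 0], dtype=np.float64)
    ssims = tuple(ssim(fi12, fakes[k]) for k in range(5))
    k_best = int(np.argmax(ssims))  # first max -> smallest k on ties
    return QualityResult(ssim_by_k=ssims, q=MOS_GRID[k_best], argmax_k=k_best + 1)


# --------------------------------------------------------------------------
# agreement metrics
# --------------------------------------------------------------------------

def _check_vectors(x, y, min_n: int):
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def _guard_variance(x, y, name: str) -> bool:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("%s undefined: an input vector has zero variance", name)
        return False
    return True


def srcc(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x, y = _check_vectors(x, y, 3)
    if not _guard_variance(x, y, "SRCC"):
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def krcc(x, y) -> float:
    """Kendall rank correlation, tau-b (tie-corrected)."""
    x, y = _check_vectors(x, y, 3)
    if not _guard_variance(x, y, "KRCC"):
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def plcc(x, y) -> float:
    """Pearson linear correlation."""
    x, y = _check_vectors(x, y, 3)
    if not _guard_variance(x, y, "PLCC"):
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x, y) -> float:
    """Root-mean-square error."""
    x, y = _check_vectors(x, y, 1)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def agreement(predicted, labels) -> AgreementReport:
    predicted = np.asarray(predicted, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    return AgreementReport(
        srcc=srcc(predicted, labels),
        krcc=krcc(predicted, labels),
        plcc=plcc(predicted, labels),
        rmse=rmse(predicted, labels),
        n=len(predicted),
    )


def evaluate(manifest: Manifest, state) -> AgreementReport:
    """Score every fused record in the manifest and report agreement with MOS."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    preds, labels = [], []
    cache: dict = {}
    for rec in manifest:
        key = (rec.mi1, rec.mi2)
        if key not in cache:
            cache[key] = (load_image(rec.mi1), load_image(rec.mi2))
        mi1, mi2 = cache[key]
        fused = load_image(rec.fused)
        preds.append(score_quality(mi1, mi2, fused, state).q)
        labels.append(rec.mos)
    return agreement(preds, labels)
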