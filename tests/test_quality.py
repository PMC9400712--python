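"""SSIM, the five-condition quality scorer, and the agreement metrics."""

import itertools

import numpy as np
import pytest

from fuseqa.quality import (
    MOS_GRID,
    QualityResult,
    agreement,
    evaluate,
    krcc,
    plcc,
    rmse,
    score_quality,
    srcc,
    ssim,
)

from oracles import (
    kendall_taub_bruteforce,
    pearson_bruteforce,
    rmse_bruteforce,
    spearman_bruteforce,
    ssim_bruteforce,
)


# ---------------------------------------------------------------------- SSIM

def test_ssim_identity_and_symmetry(rng):
    x = rng.uniform(size=(16, 16))
    y = rng.uniform(size=(16, 16))
    assert ssim(x, x) == pytest.approx(1.0)
    assert ssim(x, y) == pytest.approx(ssim(y, x))


def test_ssim_rejects_too_small_images(rng):
    with pytest.raises(ValueError):
        ssim(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))


def test_ssim_uniform_offset_matches_bruteforce():
    a = np.full((16, 16), 0.5)
    b = a + 0.2
    assert ssim(a, b) == pytest.approx(ssim_bruteforce(a, b), abs=1e-9)


def test_ssim_matches_sliding_window_oracle_on_random_images():
    for seed in range(10):
        r = np.random.default_rng(seed)
        a = r.uniform(size=(16, 16))
        b = np.clip(a + r.normal(0, 0.1, size=(16, 16)), 0, 1)
        assert ssim(a, b) == pytest.approx(ssim_bruteforce(a, b), abs=1e-9)


# ------------------------------------------------------------ quality scorer

class _StubGenerator:
    """Returns premade images per MOS condition and counts forward calls."""

    def __init__(self, images):
        self.images = np.asarray(images, dtype=np.float32)
        self.training = False
        self.calls = 0
        self.batch_sizes = []

    def eval(self):
        return self

    def train(self, mode=True):
        return self

    def forward(self, mi1, mi2, mos):
        from fuseqa._autograd import Tensor

        self.calls += 1
        self.batch_sizes.append(len(mos))
        return {"fused": Tensor(self.images[:, None]), "recon_pairs": []}


class _StubState:
    def __init__(self, images, side):
        from fuseqa.config import RunConfig

        self.generator = _StubGenerator(images)
        self.config = RunConfig(image_side=side, channel_widths=(8, 16, 32))


def test_score_quality_evaluates_exactly_five_conditions(rng):
    side = 16
    imgs = rng.uniform(size=(5, side, side))
    state = _StubState(imgs, side)
    fi = rng.uniform(size=(side, side))
    score_quality(fi, fi, fi, state)
    assert state.generator.calls == 1
    assert state.generator.batch_sizes == [5]


def test_score_quality_picks_pixel_identical_condition(rng):
    side = 16
    fi12 = rng.uniform(size=(side, side))
    imgs = rng.uniform(size=(5, side, side))
    imgs[3] = fi12  # k=4 matches exactly
    state = _StubState(imgs, side)
    res = score_quality(fi12, fi12, fi12, state)
    assert res.q == pytest.approx(0.8)
    assert res.argmax_k == 4
    assert res.ssim_by_k[3] == pytest.approx(1.0)


def test_score_quality_tie_breaks_toward_smallest_k(rng):
    side = 16
    fi12 = rng.uniform(size=(side, side))
    imgs = np.stack([fi12] * 5)  # all conditions tie at SSIM 1
    res = score_quality(fi12, fi12, fi12, _StubState(imgs, side))
    assert res.q == pytest.approx(0.2)
    assert res.argmax_k == 1


def test_score_quality_q_lies_on_grid(rng):
    side = 16
    imgs = rng.uniform(size=(5, side, side))
    res = score_quality(
        rng.uniform(size=(side, side)), rng.uniform(size=(side, side)),
        rng.uniform(size=(side, side)), _StubState(imgs, side),
    )
    assert res.q in MOS_GRID
    assert all(-1.0 <= s <= 1.0 for s in res.ssim_by_k)


def test_score_quality_autoresizes_with_warning(rng, caplog):
    side = 16
    imgs = rng.uniform(size=(5, side, side))
    big = rng.uniform(size=(32, 32))
    with caplog.at_level("WARNING", logger="fuseqa"):
        res = score_quality(big, big, big, _StubState(imgs, side))
    assert res.q in MOS_GRID
    assert any("auto-resizing" in r.message for r in caplog.records)


def test_quality_result_consistency_invariant():
    with pytest.raises(AssertionError):
        QualityResult(ssim_by_k=(0.1,) * 5, q=0.4, argmax_k=1)


# -------------------------------------------------------- agreement metrics

def test_metric_textbook_examples():
    assert srcc([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)
    assert krcc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
    x = np.array([1.0, 2.0, 5.0, 7.0])
    assert plcc(x, 3.0 * x + 1.0) == pytest.approx(1.0)


def test_metrics_match_bruteforce_on_exhaustive_small_rank_patterns():
    """All four metrics agree with direct-from-definition computation."""
    values = [0.2, 0.4, 0.6, 0.8]
    x = np.array([0.2, 0.4, 0.6, 0.8, 0.4])
    for combo in itertools.product(values, repeat=5):
        y = np.array(combo)
        if np.ptp(y) == 0:
            continue
        assert srcc(x, y) == pytest.approx(spearman_bruteforce(x, y), abs=1e-12)
        assert krcc(x, y) == pytest.approx(kendall_taub_bruteforce(x, y), abs=1e-12)
        assert plcc(x, y) == pytest.approx(pearson_bruteforce(x, y), abs=1e-12)
        assert rmse(x, y) == pytest.approx(rmse_bruteforce(x, y), abs=1e-12)


def test_zero_variance_input_returns_nan_with_warning(caplog):
    with caplog.at_level("WARNING", logger="fuseqa"):
        assert np.isnan(srcc([1, 1, 1], [1, 2, 3]))
    assert any("zero variance" in r.message for r in caplog.records)


def test_agreement_perfect_predictions():
    labels = [0.2, 0.4, 0.6, 0.8, 1.0]
    rep = agreement(labels, labels)
    assert rep.srcc == pytest.approx(1.0)
    assert rep.krcc == pytest.approx(1.0)
    assert rep.plcc == pytest.approx(1.0)
    assert rep.rmse == pytest.approx(0.0)
    assert rep.n == 5


def test_agreement_constant_predictions_reports_rmse():
    rep = agreement([0.6] * 5, [0.2, 0.4, 0.6, 0.8, 1.0])
    assert np.isnan(rep.srcc)
    assert rep.rmse == pytest.approx(rmse_bruteforce([0.6] * 5, [0.2, 0.4, 0.6, 0.8, 1.0]))


def test_evaluate_scores_every_manifest_record(phantom_dataset, rng):
    manifest, _ = phantom_dataset
    side = 48
    imgs = rng.uniform(size=(5, side, side))
    rep = evaluate(manifest, _StubState(imgs, side))
    assert rep.n == len(manifest)


def test_evaluate_empty_manifest_raises():
    from fuseqa.io import Manifest

    with pytest.raises(ValueError):
        evaluate(Manifest([]), None)
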