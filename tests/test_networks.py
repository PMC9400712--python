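"""Generator/discriminator assembly, shapes, and the adversarial losses."""

import numpy as np
import pytest

from fuseqa.config import RunConfig
from fuseqa.networks import (
    build_discriminator,
    build_generator,
    discriminate,
    generate,
    loss_D,
    loss_fusion,
    loss_G,
    score_map_side,
)
from fuseqa.training import init_state

from conftest import tiny_config
from oracles import loss_d_bruteforce, loss_fusion_bruteforce, loss_g_bruteforce


def test_generator_output_matches_image_side(small_state, rng):
    side = small_state.config.image_side
    mi1 = rng.uniform(size=(2, side, side))
    mi2 = rng.uniform(size=(2, side, side))
    out = small_state.generator.forward(mi1, mi2, np.array([0.4, 0.8]))
    assert out["fused"].shape == (2, 1, side, side)
    assert out["fused"].data.min() >= 0.0 and out["fused"].data.max() <= 1.0
    assert len(out["recon_pairs"]) == 2  # both modalities reconstructed


def test_generate_single_image_deterministic(small_state, rng):
    side = small_state.config.image_side
    mi1 = rng.uniform(size=(side, side))
    mi2 = rng.uniform(size=(side, side))
    a = generate(mi1, mi2, 0.6, small_state)
    b = generate(mi1, mi2, 0.6, small_state)
    assert a.fused.shape == (side, side)
    assert np.array_equal(a.fused, b.fused)


def test_generator_rejects_mismatched_inputs(small_state, rng):
    side = small_state.config.image_side
    with pytest.raises(ValueError):
        small_state.generator.forward(
            rng.uniform(size=(1, side, side)),
            rng.uniform(size=(1, side // 2, side // 2)),
            np.array([0.5]),
        )


@pytest.mark.parametrize("image_side,expected", [(128, 6), (96, 4), (64, 2), (48, 1)])
def test_score_map_side_table(image_side, expected):
    assert score_map_side(image_side) == expected


@pytest.mark.parametrize("image_side,expected", [(64, 2), (96, 4)])
def test_discriminator_score_map_shape(image_side, expected, rng):
    cfg = RunConfig(image_side=image_side, channel_widths=(8, 16, 32),
                    disc_widths=(4, 8, 16, 32))
    disc = build_discriminator(cfg)
    disc.eval()
    scores = disc.forward(rng.uniform(size=(1, 1, image_side, image_side)), np.array([0.5]))
    assert scores.shape == (1, 1, expected, expected)


def test_each_db_quarters_the_feature_map_area(rng):
    cfg = RunConfig(image_side=64, channel_widths=(8, 16, 32), disc_widths=(4, 8, 16, 32))
    disc = build_discriminator(cfg)
    disc.eval()
    from fuseqa.networks import _with_mos_plane

    x = _with_mos_plane(rng.uniform(size=(1, 1, 64, 64)), np.array([0.5]))
    areas = []
    for b in disc.blocks:
        x = b(x)
        areas.append(x.shape[-1] * x.shape[-2])
    assert len(areas) == 4
    assert all(a2 * 4 == a1 for a1, a2 in zip([64 * 64] + areas[:-1], areas))


def test_discriminator_rejects_wrong_side(rng):
    cfg = tiny_config()
    disc = build_discriminator(cfg)
    with pytest.raises(ValueError):
        disc.forward(rng.uniform(size=(1, 1, 32, 32)), np.array([0.5]))


def test_generator_discriminator_compose(small_state, rng):
    side = small_state.config.image_side
    mi1 = rng.uniform(size=(side, side))
    mi2 = rng.uniform(size=(side, side))
    fused = generate(mi1, mi2, 0.6, small_state).fused
    scores = discriminate(fused, 0.6, small_state)
    m = score_map_side(side)
    assert scores.shape == (m, m)
    assert np.all(np.isfinite(scores))


# ------------------------------------------------------------------- losses

def test_loss_fusion_examples_and_oracle(rng):
    x = rng.uniform(size=(1, 1, 8, 8))
    assert loss_fusion(x, x).item() == 0.0
    y_true = np.ones((2, 2))
    y_hat = np.array([[0.0, 1.0], [1.0, 1.0]])
    assert loss_fusion(y_true, y_hat).item() == pytest.approx(0.25)
    a, b = rng.uniform(size=(4, 4)), rng.uniform(size=(4, 4))
    assert loss_fusion(a, b).item() == pytest.approx(loss_fusion(b, a).item())
    assert loss_fusion(a, b).item() == pytest.approx(loss_fusion_bruteforce(a, b), abs=1e-6)


def test_loss_g_examples_and_oracle(rng):
    ones = np.ones((2, 2))
    assert loss_G(ones, 0.0, alpha=100.0).item() == pytest.approx(0.0)
    assert loss_G(np.zeros((2, 2)), 0.0, alpha=100.0).item() == pytest.approx(1.0)
    assert loss_G(ones, 0.01, alpha=100.0).item() == pytest.approx(1.0)
    s = rng.uniform(-1, 2, size=(3, 3))
    assert loss_G(s, 0.07, alpha=50.0).item() == pytest.approx(
        loss_g_bruteforce(s, 0.07, 50.0), abs=1e-5
    )


def test_loss_g_monotone_in_fusion_term(rng):
    s = rng.uniform(size=(3, 3))
    assert loss_G(s, 0.2, alpha=10.0).item() > loss_G(s, 0.1, alpha=10.0).item()


def test_loss_d_examples_and_oracle(rng):
    ones, zeros = np.ones((2, 2)), np.zeros((2, 2))
    assert loss_D(ones, zeros).item() == pytest.approx(0.0)
    assert loss_D(zeros, ones).item() == pytest.approx(1.0)
    half = np.full((2, 2), 0.5)
    assert loss_D(half, half).item() == pytest.approx(0.25)
    r, f = rng.uniform(size=(3, 3)), rng.uniform(size=(3, 3))
    assert loss_D(r, f).item() == pytest.approx(loss_d_bruteforce(r, f), abs=1e-6)


def test_log_form_losses_finite(rng):
    s = rng.normal(size=(3, 3))
    assert np.isfinite(loss_G(s, 0.1, alpha=1.0, form="log").item())
    assert np.isfinite(loss_D(s, -s, form="log").item())


def test_alpha_must_be_positive(rng):
    with pytest.raises(ValueError):
        loss_G(np.ones((2, 2)), 0.0, alpha=0.0)
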