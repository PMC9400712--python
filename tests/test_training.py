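"""Training loop: step semantics, determinism, splits, checkpoints, ablations."""

import numpy as np
import pytest

from fuseqa._autograd import Tensor
from fuseqa.encoder_decoder import loss_ed
from fuseqa.model import FusionQualityModel
from fuseqa.networks import loss_fusion, loss_G
from fuseqa.training import (
    build_ablation,
    init_state,
    load_checkpoint,
    load_samples,
    save_checkpoint,
    split_by_pair,
    train_step,
)

from conftest import tiny_config


@pytest.fixture(scope="module")
def samples():
    from fuseqa.phantoms import PhantomSpec, make_dataset
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        manifest = make_dataset(PhantomSpec(side=48, n_pairs=2, seed=3), d)
        return load_samples(manifest, 48)


def _all_params(state):
    return state.generator.parameters() + state.discriminator.parameters()


def test_zero_learning_rate_step_is_noop(samples):
    state = init_state(tiny_config(learning_rate=0.0))
    before = [p.data.copy() for p in _all_params(state)]
    train_step(samples[:4], state)
    after = [p.data for p in _all_params(state)]
    for b, a in zip(before, after):
        assert np.array_equal(b, a)


def test_train_step_is_deterministic_given_seed(samples):
    losses = []
    for _ in range(2):
        state = init_state(tiny_config())
        losses.append(train_step(samples[:4], state))
    assert losses[0] == losses[1]


def test_reconstruction_loss_trends_down_over_steps(samples):
    """After 50 steps on a 10-sample set the encoder-decoders reconstruct better."""
    state = init_state(tiny_config(batch_size=5))
    subset = samples[:10]
    first = train_step(subset[:5], state)["loss_ED"]
    last = None
    for i in range(49):
        batch = subset[:5] if i % 2 else subset[5:]
        last = train_step(batch, state)["loss_ED"]
    assert last < first


def test_split_keeps_pairs_together(samples):
    train, val = split_by_pair(samples, 0.5, seed=0)
    train_pairs = {s.pair_key for s in train}
    val_pairs = {s.pair_key for s in val}
    assert train_pairs.isdisjoint(val_pairs)
    assert len(train) + len(val) == len(samples)
    # deterministic
    train2, val2 = split_by_pair(samples, 0.5, seed=0)
    assert [s.mos for s in val2] == [s.mos for s in val]


def test_beta_scales_encoder_decoder_gradient(samples):
    """Doubling beta doubles the L_ED contribution to the decoder gradient."""
    grads = {}
    for beta in (10.0, 20.0):
        state = init_state(tiny_config(beta=beta))
        mi1 = np.stack([s.mi1 for s in samples[:2]]).astype(np.float32)
        mi2 = np.stack([s.mi2 for s in samples[:2]]).astype(np.float32)
        mos = np.array([s.mos for s in samples[:2]], dtype=np.float32)
        out = state.generator.forward(mi1, mi2, mos)
        l_ed = loss_ed(out["recon_pairs"])
        n = sum(o.data.size for o, _ in out["recon_pairs"])
        total = beta * (l_ed / float(n))
        for p in state.generator.parameters():
            p.grad = None
        total.backward()
        w = state.generator.decoder1.out.weight
        grads[beta] = w.grad.copy()
    assert np.allclose(grads[20.0], 2.0 * grads[10.0], rtol=1e-4, atol=1e-8)


def test_nonfinite_loss_aborts_with_term_name(samples):
    state = init_state(tiny_config())
    # poison a generator weight so the forward pass produces non-finite values
    state.generator.head.weight.data[:] = np.nan
    with pytest.raises(FloatingPointError, match="loss"):
        train_step(samples[:2], state)


def test_short_training_run_history_and_best_selection(phantom_dataset):
    manifest, _ = phantom_dataset
    cfg = tiny_config(epochs=2)
    results = FusionQualityModel(manifest, cfg).fit()
    hist = results.history
    assert len(hist) == 2
    assert np.isfinite(hist[["loss_G", "loss_D", "loss_ED", "val_rmse"]].to_numpy()).all()
    assert results.state.best_srcc == pytest.approx(hist["val_srcc"].max())
    assert results.state.best_epoch == int(hist["val_srcc"].idxmax())


def test_training_is_reproducible(phantom_dataset):
    manifest, _ = phantom_dataset
    cfg = tiny_config(epochs=1)
    h1 = FusionQualityModel(manifest, cfg).fit().history
    h2 = FusionQualityModel(manifest, cfg).fit().history
    assert h1.equals(h2)


def test_checkpoint_roundtrip_preserves_forward(tmp_path, samples):
    state = init_state(tiny_config())
    train_step(samples[:4], state)  # move off initialization
    path = tmp_path / "ckpt.npz"
    save_checkpoint(state, path)
    restored = load_checkpoint(path)
    mi1, mi2 = samples[0].mi1, samples[0].mi2
    from fuseqa.networks import generate

    a = generate(mi1, mi2, 0.6, state).fused
    b = generate(mi1, mi2, 0.6, restored).fused
    assert np.array_equal(a, b)
    assert restored.config == state.config


def test_checkpoint_rejects_foreign_file(tmp_path):
    np.savez(tmp_path / "x.npz", __meta__=np.frombuffer(b'{"magic": "no"}', dtype=np.uint8))
    with pytest.raises(ValueError, match="checkpoint"):
        load_checkpoint(tmp_path / "x.npz")


# ----------------------------------------------------------------- ablations

def test_early_mode_builds_single_encoder():
    gen = build_ablation(tiny_config(fusion_mode="early"))
    assert hasattr(gen, "encoder") and not hasattr(gen, "encoder1")
    assert not hasattr(gen, "down_blocks")


def test_late_mode_fuses_only_level3_features():
    gen = build_ablation(tiny_config(fusion_mode="late"))
    assert hasattr(gen, "encoder1") and hasattr(gen, "encoder2")
    assert hasattr(gen, "fuse_block") and not hasattr(gen, "down_blocks")


def test_hierarchical_mode_has_three_down_and_three_up_blocks():
    gen = build_ablation(tiny_config())
    assert len(gen.down_blocks) == 3 and len(gen.up_blocks) == 3


def test_without_sa_equals_sa_forward_at_zero_gamma(rng):
    cfg_sa = tiny_config(use_sa=True)
    cfg_no = tiny_config(use_sa=False)
    gen_sa = build_ablation(cfg_sa)
    gen_no = build_ablation(cfg_no)
    shared = {k: v for k, v in gen_sa.state_dict().items() if ".sa." not in k}
    gen_no.load_state_dict(shared)
    gen_sa.eval(), gen_no.eval()
    side = cfg_sa.image_side
    mi1 = rng.uniform(size=(1, side, side))
    mi2 = rng.uniform(size=(1, side, side))
    a = gen_sa.forward(mi1, mi2, np.array([0.4]))["fused"].data
    b = gen_no.forward(mi1, mi2, np.array([0.4]))["fused"].data
    assert np.allclose(a, b, atol=1e-6)


@pytest.mark.parametrize("mode", ["early", "late"])
def test_ablation_modes_generate_correct_shape(mode, rng):
    cfg = tiny_config(fusion_mode=mode)
    state = init_state(cfg)
    side = cfg.image_side
    out = state.generator.forward(
        rng.uniform(size=(1, side, side)), rng.uniform(size=(1, side, side)),
        np.array([0.6]),
    )
    assert out["fused"].shape == (1, 1, side, side)
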