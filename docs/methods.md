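# Methods

## Model

`fuseqa` scores the quality of a multimodal fused image with a conditional
GAN. The conditioning signal is the normalized mean opinion score
(MOS ∈ [0, 1]; a 1–5 radiologist scale divided by 5, so the five grid
points are MOS_k = 0.2k). The generator learns the map
(MI₁, MI₂, mos) → fused image of that quality; at assessment time the
image under test is compared (by SSIM) against the five conditioned
generations and the best-matching condition is returned as the quality
call. The assumption underlying the method is that generated image
fidelity varies monotonically with the conditioning MOS once the
adversarial/reconstruction objectives converge, so the SSIM argmax
identifies the test image's quality level.

### Components

* **Conditioning.** A scalar MOS joins an image as a constant-valued extra
  channel. This preserves spatial structure and makes the conditioning
  visible to every convolution.
* **Dual-channel encoder-decoder.** One encoder per modality, three blocks
  of [conv 3×3/s1/p1 → batch-norm → leaky ReLU(0.2)] ×2 + max-pool 2×2,
  widths (32, 64, 128) by default (paper-silent; configurable). Block j
  emits the pyramid level F_ij of side S/2ʲ. The decoder consumes only the
  deepest level (no skip connections) through seven transposed-convolution
  groups — three stride-2 groups (kernel 4, the clean 2× upsampling) and
  four stride-1 refiners (kernel 3), interleaved s1,s2,s1,s2,s1,s2,s1 —
  which is the only arrangement that bridges S/8 → S with seven groups.
  L_ED is the raw summed absolute reconstruction error over both
  modalities.
* **Self-attention fusion (SA-FB).** Per level: concat(F₁ⱼ, F₂ⱼ) →
  self-attention → conv 1×1 (channel-preserving) → concat with the running
  fusion state → conv 3×3. Down-path blocks append BN + leaky ReLU +
  max-pool; up-path blocks use ReLU and no pool. The attention operator is
  the standard query/key/value form with query/key at channels/8, a
  row-softmax (max-subtracted, overflow-safe) over key positions, and a
  learned scalar gate γ initialized to 0 — so a fresh block is exactly the
  identity, which stabilizes GAN warm-up and gives a free structural test.
  The up path re-consumes the pyramid features of the matching level while
  the fusion state is nearest-neighbour upsampled between levels; three
  up-path blocks mirror the three pyramid levels. A final linear conv
  produces the fused image, clipped to [0, 1].
* **Discriminator.** Candidate image + MOS plane through four blocks of
  conv 3×3/s2/p1 → BN → leaky ReLU (widths (64, 128, 256, 512) by default)
  and a final unpadded 3×3 conv: 128 → 64 → 32 → 16 → 8 → 6, a 6×6 score
  map. Padding 0 in the final conv is the only reading that yields 6×6.
  The discriminator sees only the candidate and the MOS, not the source
  images (a source-conditioned variant is not implemented; the
  candidate+MOS form matches the objective actually optimized).

### Objectives

The adversarial game is least-squares (targets 1 real / 0 fake): the
written objectives are in log form but the loss actually applied is mean
square error, and the least-squares form is free of log-of-zero issues for
scores in any range. The log form is retained behind
`RunConfig.adversarial_form = "log"` (scores through a sigmoid) for
fidelity experiments.

* L_fusion = batch-mean |y_true − ŷ| ("N" read as the batch size — the
  only reading that makes it a per-step loss).
* L_G = mean (D(ŷ|mos) − 1)² + α·L_fusion, α = 100.
* L_D = ½ [mean (D(y|mos) − 1)² + mean D(ŷ|mos)²] (the two expectation
  terms summed).
* Total: L_G + β·L_ED_norm with β = 20. L_ED is defined as a raw sum;
  the training loop divides it by the number of reconstructed pixels
  before applying β so the default weight is stable across image sides.
  `loss_ed` itself still reports the raw sum.
* One discriminator step then one generator step per batch; Adam with
  lr 2e-4 and betas (0.5, 0.999) — the de-facto conditional-GAN recipe.
  L_ED's gradient reaches only the encoder-decoder parameters (the fusion
  path is trained by the adversarial/fusion terms alone, which falls out
  of the architecture: the decoders branch off before the fusion blocks).

### Checkpoint selection

The manifest is split 80/20 **by source pair** (all five fusions of a pair
stay on one side) to prevent leakage of pair content into validation. The
model is evaluated after every epoch by running the full five-condition
scorer on the validation fusions; the checkpoint with the highest
validation SRCC is returned. Undefined correlations (constant predictions,
typical of the first epochs) are recorded as 0 in the history so all
entries stay finite.

## Numerical core

No deep-learning framework is used: the networks run on a small in-package
reverse-mode autodiff over numpy float32 arrays (im2col convolutions,
adjoint-based transposed convolutions, 2×2 max pooling, batch
normalization with running statistics in inference mode, batched matmul
attention). Every backward rule is verified against central finite
differences in the test suite. Determinism: all randomness flows through
`numpy.random.Generator` instances seeded from the run seed; repeated runs
are bit-identical.

Numerical choices worth knowing:

* The generator output is a linear conv clipped to [0, 1] (no sigmoid);
  the clip passes gradient on the closed interval and the output bias is
  initialized to 0.5 so training does not start in a dead all-clipped
  regime.
* Softmax uses max-subtraction; attention is finite for any finite input.
* Batch-norm uses biased batch variance in training and running statistics
  in inference; inference is therefore deterministic.
* Eq.-6-style tie-breaks go to the smallest MOS condition (a conservative,
  pessimistic quality call).
* SSIM uses the original settings: 11×11 Gaussian window (σ = 1.5),
  K₁ = 0.01, K₂ = 0.03, dynamic range 1 (delegated to
  scikit-image; validated against a sliding-window oracle to 1e-9).
  KRCC is Kendall tau-b, since grid-valued predictions guarantee ties.

## Synthetic phantoms

The radiologist-scored fusion database the method was designed around is
not publicly available, so training and evaluation run on a synthetic
stand-in that reproduces its structure, not its content:

* structural phantom: bright skull-analogue ring, 2–5 sharp-edged interior
  ellipses with distinct intensities (≥3 histogram modes);
* functional phantom: 3–6 smooth Gaussian hotspots whose centres are drawn
  from the ring interior of its structural partner (registration by
  construction), with lower mean gradient than the structural image;
* reference fusion: pixelwise maximum (simple, monotone, preserves both
  modalities' salient content);
* graded degradations at levels L ∈ {0, 0.2, 0.4, 0.6, 0.8}: Gaussian blur
  (σ = 3L) → additive Gaussian noise (sd = 0.1L) → contrast compression
  toward the mean (factor 0.5L), in that fixed order, clipped to [0, 1];
  level 0 is the exact identity. Level k carries MOS 1.0 − 0.2k, so MOS is
  tied deterministically to degradation strength and each grid value
  appears equally often.

What the phantoms do **not** emulate: real anatomy and pathology, the
behaviour of actual fusion algorithms (artifacts are limited to blur,
noise and contrast loss), colour functional overlays, and inter-rater
variability — MOS here is noise-free. Passing tests therefore demonstrate
that the pipeline can recover a known quality ordering from image content,
not that it matches radiologist judgement on clinical data.

## Problem sizes

The default configuration mirrors the full-scale setting (side 128, widths
(32, 64, 128), 200 epochs with best-checkpoint selection). The package's
own end-to-end demonstrations use a reduced scale chosen to keep a CPU run
in minutes while leaving the architecture ratios intact: side 64, widths
(16, 32, 64), discriminator widths (16, 32, 64, 128), 20 phantom pairs
(100 fusion samples, 80/20 split), 15 epochs, batch 8, seed 0. At that
scale validation SRCC reaches 1.0 within a handful of epochs (see the
worked example in the README); the acceptance script reruns this from
scratch.

## Known limitations

* The synthetic MOS marginal is uniform over the five levels; real score
  distributions are skewed and noisy.
* The quality call is grid-valued (the argmax condition, no
  interpolation), so resolution is limited to 0.2 on the normalized scale.
* Early/late-fusion ablation modes reconstruct through the same decoder
  machinery but are wired for comparison studies, not production scoring.
* Non-square inputs are rejected rather than padded; colour inputs are
  reduced to ITU-R 601 luminance.
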