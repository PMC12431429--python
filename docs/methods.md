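# Methods

This note documents the model, the synthetic data it is exercised on, and
the numerical choices that shape both.

## The estimation problem

Continuous vigilance is summarised by PERCLOS (percentage of eyelid closure
per unit time), a label in [0, 1] recorded once per minute alongside
precomputed frequency-domain features from two physiological modalities:
EEG, as full-band spectra (1–50 Hz at 2 Hz resolution, 17 channels, PSD and
DE feature types flattened to 4 × 425 per sample) and as five-band powers
(4 × 85), and EOG eye-movement features (3 × 36).  The task is cross-subject
regression: predict a new subject's PERCLOS from models trained on other
subjects, under leave-one-subject-out (LOSO) evaluation.

## Network

Each modality has its own encoder.  A sample's tensor is treated as a short
sequence over its feature-type rows (4, 3 and 4 steps respectively) whose
per-step channels are the flattened spectral features (425/36/85) — this is
the axis convention under which the published forward-pass budget of
~0.003 GFLOPs is reproduced (our analytic count: 0.0026 GFLOPs).  The
encoder applies two causal 1-D convolutions (to 16, then 64 channels for
EEG / 32 for EOG; kernel 3; left-only zero padding by default, symmetric
replication padding available), each followed by ReLU and a
ConvSparseAttention block (channel compression, depthwise + pointwise
convolution, softmax-normalised multi-head attention, a parallel
conv–batchnorm–ReLU path multiplied in, and a residual connection).  A
2-layer post-norm Transformer (4 heads, FFN 128, dropout 0.3, learned
positional embeddings) over the steps plus a learned CLS token yields the
sample summary, from which two linear heads produce the predictive mean and
the log predictive variance (exponentiated, so variance is always
positive).  In training mode the sampled prediction is `mu + sigma^2 * eps`
with standard-normal `eps`, implemented literally as written with a
`noise_mode="std"` switch for the conventional reparameterisation; in
evaluation it equals the mean.

Fusion projects the three CLS features to a shared 64-d space, converts the
three variances to precisions `pi_i = 1/(sigma_i^2 + 1e-8)` and normalised
confidence weights `w_i`, and runs 4-head attention over the three modality
tokens.  Attention rows are softmax-normalised, multiplied along the key
axis by a softmax of `beta = 0.5` times a learned projection of the
confidence weights, and renormalised; a literal variant (raw scaled scores
times the confidence softmax, no renormalisation) is available.  The
confidence weights are constants under differentiation, so the network
cannot court lower loss by inflating variances.  The head outputs are
concatenated, projected and averaged over modality positions.  A
multi-scale extractor (6 → 32 → LayerNorm → 64 → dropout) processes the
vector of three sampled predictions and three variances, a two-layer
sigmoid MLP gates the attended feature, and the final prediction is the sum
of a fused branch on the gated feature and a residual branch on the
6-vector.

## Objective

Per modality, a heteroscedastic Gaussian negative log-likelihood
`0.5 log s^2 + 0.5 (mu - y)^2 / s^2 + 0.001 s^2`, combined across
modalities with per-sample precision weights (detached); plus the MSE of
the final prediction and auxiliary branch supervision, totalling
`1.0 * L_unimodal + 1.0 * L_fusion + 0.5 * L_aux`.

Two compositions of the auxiliary term exist in the package.  The written
form supervises both branches directly on the label; because the branch
*sum* is also supervised on the label, that composition is minimised at
`y_fusion = 1.2 y` — a 20% multiplicative bias (set the derivative of
`(f + r - y)^2 + 0.5 (f - y)^2 + 0.5 (r - y)^2` to zero).  The default is
therefore the residual-learning composition: the fused branch is supervised
on the label and the residual branch on the label minus the (detached)
fused output, which leaves the exact additivity `y_fusion = y_fused +
y_residual` intact and makes the final prediction unbiased.  The literal
form remains available as `LossConfig(aux_mode="label")`.

Two stabilisations matter in practice.  The variance heads are initialised
near a constant prior variance of 0.1 (near-zero weights), so all
modalities start equally confident.  And the first epochs (5 of the default
50; 10 in the bundled benchmark, where heads must calibrate on less data)
use uniform loss weights before the precision weighting activates.  Without
these, the weighting exhibits a rich-get-richer failure mode: a modality
whose variance rises early loses its loss weight, which throttles both its
mean training (gradient ∝ w) and its variance recovery (gradient ∝ 1/s²),
freezing it permanently.  Neither choice changes the converged objective.

## Training and inference

AdamW (decoupled weight decay 1e-2) with one parameter group per module:
learning rates 4e-4 (EEG-2Hz), 7e-4 (EEG-5Bands), 3e-4 (EOG), 5e-4
(fusion); batch size 128 and 50 epochs by default.  All randomness derives
from one seed; training is bitwise reproducible on a given platform (exact
reproducibility across BLAS implementations is not guaranteed).

Predictive uncertainty uses Monte-Carlo dropout: 10 stochastic forward
passes with dropout active (rate 0.3).  The prediction is the mean of the
passes and the epistemic variance is their variance, computed with shifted
moments so that with dropout disabled the mean equals the deterministic
forward pass bitwise and the variance is exactly zero.  Normalisation
layers keep their running statistics and the Gaussian head noise stays off
during MC sampling (a flag re-enables it), so dropout is the only
stochasticity.  An aleatoric proxy — the MC average of the
precision-weighted unimodal variances — is reported alongside; the headline
uncertainty is the across-pass variance.

The operation counter totals the multiply–accumulates of every linear,
convolutional and attention product (2 FLOPs per MAC, batch size 1);
activations and normalisations are not counted, following the usual
profiler convention.

## Synthetic data

The simulator generates the statistical structure the network assumes,
per subject: a latent fatigue trajectory from an exactly discretised
Ornstein–Uhlenbeck process in logit space (mean-reversion rate 0.01 per
minute-sample, diffusion 0.15, started at a per-subject baseline) squashed
through a logistic — slow, bounded, continuous drift; labels are the latent
plus clipped N(0, 0.02²) noise.  Each modality observes four basis
functions of the latent (z, z², sin 2πz, cos 2πz) through independent
Gaussian noise per coordinate, expanded into the published feature shapes
by a fixed, seed-determined, orthonormalised random linear map, plus
per-cell sensor noise at half the coordinate scale.  Independence per
coordinate matters: noise confined to one scalar direction would be
recoverable from the redundant coordinates, and amplifying it would add
information rather than destroy it.

The noise scales (EOG 0.26, EEG-2Hz 0.35, EEG-5Bands 0.45) are calibrated
so that single-modality regressors on held-out subjects reproduce the
published relative errors — EOG best, EEG-2Hz ≈ 1.4× and EEG-5Bands ≈ 1.7×
the EOG error, with seed-to-seed spread — while leaving every modality
clearly above the shared label-noise floor, so multimodal combination has
measurable headroom, as it does in the published comparison.  Artifacts are
modelled by scaling all noise of a randomly chosen sample subset around the
stored noise-free signal (default study condition: EEG-2Hz, rate 0.3, gain
10, echoing reported EEG contamination rates); corrupted samples stay on
the data manifold and labels are untouched.

What the simulator does not emulate: volume conduction and channel
covariance structure, subject-specific feature-to-vigilance mappings
(the mixing map is shared across subjects, so cross-subject transfer is
easier than in real recordings), non-stationary noise, and real artifact
morphology.  Passing tests on this data therefore demonstrate the
estimation machinery — calibration of variance heads, uncertainty-weighted
fusion, LOSO plumbing — not performance on SEED-VIG-like recordings.

## Desk-scale benchmark

The bundled benchmark (`vigilnet.benchmark.run_corrupted_benchmark`)
trains the trimodal network and the three unimodal encoders identically on
a 6-subject dataset — 885 samples per subject, one subject held out
(rotating with the seed), EEG-2Hz corrupted at rate 0.3 / gain 10 — for 40
epochs at batch size 64 with an 8-epoch uniform-weight warm-up.  The
problem sizes are deliberate: five training subjects rather than the bare
minimum because with very few subjects the dominant held-out error is a
label-distribution-shift bias common to all modalities, which no fusion
can reduce (the emulated study trains on 22 subjects); batch 64 rather
than 128 doubles the optimiser steps on the 4,425-sample training folds;
and 40 epochs is where the fused head has converged while the strongest
unimodal encoder begins to overfit, on one CPU in a few minutes per seed.
Expected behaviour, verified by the acceptance tests across three seeds:
the fused model's held-out RMSE is below every unimodal encoder's, and on
artifact-masked test samples the corrupted modality receives the smallest
mean confidence weight of the three (typically under 0.07 against 0.25+
on clean samples of the same fold).

## Known limitations

* The numerics layer is a purpose-built NumPy autodiff engine; it is exact
  (float64, finite-difference-verified) but single-threaded and far slower
  than GPU frameworks, so all shipped problem sizes are desk scale.
* Under the literal-form settings (`aux_mode="label"`,
  `attention_variant="literal"`) the package reproduces the written
  formulas as printed, including the branch-sum bias analysed above; these
  settings are for study, not use.
* The head-count discrepancy in the sources (4 in the equations, 3 in the
  prose) is resolved as 4, since 3 does not divide the 64-d fusion space;
  `n_heads` is configurable.
* MC-dropout epistemic variance is a heuristic; it is validated here only
  for its contractual properties (zero without dropout, growth with rate),
  not as a calibrated uncertainty.
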