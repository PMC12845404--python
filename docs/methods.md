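# Methods

This note documents the models and procedures implemented in `apyield`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Problem setting

The unit of prediction is a county-year: a matrix of 7 months (April–
October) × 18 temporal channels — Sentinel-2 bands B2, B4, B8, B11, B12;
11 FLDAS environmental variables; NDVI and EVI — plus county code, year
code and planting area (mu), with a yield label in kg/mu.  Monthly channel
values are median composites of all valid within-month observations (even
counts use the mean of the central pair; a month with no valid observation
is an error, never imputed).  NDVI and EVI use the standard Sentinel-2
formulations, NDVI = (B8−B4)/(B8+B4) and
EVI = 2.5·(B8−B4)/(B8+6·B4−7.5·B2+1).

Dataset splits: the most recent season (2023 by default) is the test set;
remaining county-years are shuffled (seeded) 8:2 into train/validation with
round-half-up on the train share.  Image-set splits use the 8:1:1 rule
val = test = round-half-up(n/10), train = remainder — the only rounding
consistent with both published split tables (6826 → 5460/683/683,
10914 → 8732/1091/1091).

## Regression network

Per sample, the 7×18 block is processed as:

1. **RevIN.**  Per-sample, per-channel standardization over the month axis
   with a learnable affine (std floored at ε = 1e−5, the global epsilon
   used wherever a division occurs).  The network's output is a scalar, so
   there is no output series to denormalize; instead the removed statistics
   (per-channel mean and sd, z-scored by training statistics) are
   concatenated into the regression head.  This is the scalar-head analogue
   of RevIN's reversibility; without it the level information that largely
   determines yield would be unrecoverable.
2. **Per-group TCN.**  Channels are split into spectral (5), environmental
   (11) and vegetation (2) groups; each gets its own stack of causal
   dilated 1-D convolutions (2 residual blocks, kernel 3, dilations 1 and
   2, hidden width 32 — receptive field 7 matches the 7-month window).
   Causality is contract-tested: perturbing month t never changes outputs
   before t.
3. **Adaptive spectral block (ASB).**  DFT along time (realized as constant
   DFT matrices, so gradients flow through plain matrix products and the
   identity configuration round-trips to < 1e−6), learnable complex
   per-bin/per-channel weights, a learned multiplicative boost (1+s) on the
   k = 2 largest-amplitude bins of the upper half-spectrum (selection is
   data-dependent and treated as constant in the backward pass), and a
   learnable residual mix with the input.  Unit weights, k = 0 and zero
   residual coefficient give the exact identity.
4. **Grouped fusion (GIFM).**  Per group: GLU-style gated convolution, then
   single-head self-attention over the 7 time tokens (residual).  A learned
   query attends over channels of the time-pooled representation to
   compress each group to a single scalar token; each token is added back
   to its own group (the cross-group exchange happens in the fusion step).
   Sigmoid gates computed from the three tokens weight the sum of the three
   group encodings.  Forcing the gates to (1,0,0) provably isolates group 1
   (zero gradient to the others).
5. **Multi-scale 1-D CNN.**  Parallel convolutions with kernels 3/5/7
   (edge-padded so a constant series maps to a constant response), global
   average pooling per branch, softmax-weighted combination with learnable
   branch logits (equal logits = arithmetic mean).
6. **Head.**  Concatenation of the pooled vector, the z-scored RevIN
   statistics, 8-dim learned county and year embeddings (zero-initialized
   so unseen codes contribute a neutral vector; year code = calendar year
   mod 100) and the z-scored planting area, through a one-hidden-layer MLP
   (width 64, ReLU) plus a purely linear bypass to one scalar.  Labels are
   z-scored for training and de-scaled for prediction.  The linear bypass
   keeps a linear yield response trivially reachable by the optimizer.

Dropout defaults to 0: training sets in the intended regime are tens of
samples, and dropout measurably degraded validation-based model selection.
Eval mode is exactly deterministic on CPU; all initialization randomness
comes from one seeded generator.

## Training protocol

Adam (lr 1e−3, weight decay 0.05), MSE loss, batch size 32, at most 500
epochs, early stopping on validation loss with patience 20, best-validation
parameters restored.  Learning-rate plateau scheduling (factor 0.5,
patience 5, min 1e−6) monitors the *training* loss: with ~10-sample
validation sets a validation-monitored scheduler collapses the learning
rate on noise long before convergence, while early stopping (which should
guard generalization) stays on validation.  The weight decay value was
chosen for the small-sample regime, where an unregularized fit of ~20
effective linear degrees of freedom on ~40 samples generalizes poorly.

Metrics: MAE, RMSE, MAPE (percent; zero labels excluded and counted — they
do not occur in realistic yield data) and R² (explicit `undefined` marker
when the label variance is zero).  Uncertainty: percentile bootstrap over
prediction–label pairs, 1000 replicates by default, reported as replicate
mean ± half the 2.5–97.5 percentile spread; replicates with constant labels
skip R² with a logged count.  The percentile (not BCa) bootstrap matches
the mean-±-half-width reporting convention.

## Augmentation

Applied to training years only, never the held-out season:

* **Noise:** each feature cell gains N(0, (0.01·sd)²) noise, sd computed
  across records per (month, channel) cell and for planting area; labels
  and codes are untouched.  County/year codes are never noised; whether
  planting area is noised is configurable (default yes).
* **Constrained Mixup:** pairs from the same county with label difference
  ≤ 10 % of the within-county label sd are combined as λ·a + (1−λ)·b on
  features, area and label, λ ~ Beta(0.4, 0.4) (the beta shape is
  configurable; the distribution family is fixed, its parameters were not
  published).  One accepted sample per original record, up to 50 pair
  redraws.
* **Tabular VAE:** a Gaussian-latent autoencoder (latent 8, hidden 64,
  tanh; loss = reconstruction MSE + 0.1·KL; Adam, 200 epochs default) on
  the flattened, column-standardized table, fit on the union of the mixup
  and noise outputs.  Sampling redraws latents until the requested number
  of decoded rows falls inside every column's observed range expanded by
  10 % — a concrete realization of "samples conforming to the
  distribution".  County/year columns are decoded continuously and rounded
  to the nearest observed code.

## Detection feature blocks

The fruit-detector modules are implemented as standalone operators on
[B, C, H, W] tensors with documented channel transitions; none resizes its
input implicitly (any neck-level resizing is the caller's job).

* **SS2D** uses a non-selective diagonal linear SSM per scan direction
  (|A| ≤ 1 at init); the contract honored is the four-direction scan +
  recurrence + sum, verified against a hand-unrolled recurrence.
* **GLICM** applies its axial/channel attention sequentially (H-axis →
  W-axis → channel); the attention can be forced to 1 to expose the
  conv + SS2D branch sum.
* **FMA/F-SPPF**: spatial DFTs again use constant DFT matrices; with a unit
  filter the spectral path is an exact round trip, making F-SPPF equal a
  plain SPPF (verified against an independent scipy-based oracle).
* **IAFM** follows the published composition literally,
  including the output stack applied innermost-first
  (GELU → BN → conv → depthwise → pointwise → GELU → BN → conv).  ConvAttn
  uses a 7×7 depthwise kernel and SHSA a query/key reduction of 2 (both
  configurable; the sources do not fix them).  Channel shuffle uses g = 2
  groups, the two fused inputs.
* BN uses batch statistics in training and running statistics in eval.

A toy single-scale detector (stem conv → GLICM → F-SPPF → IAFM → 5-channel
grid head) overfits 12 synthetic 16×16 gaussian-blob images to training
mAP50 ≥ 0.9 in ~300 Adam steps on one CPU core — an end-to-end smoke test
of gradient flow and expressiveness at desk scale, not a detection
benchmark.

## Proportional correction

`α = Y_true_sample / Y_pre_sample`, `Y_pre_end = α·Y_pre`, with
`Y_true_sample = (Σ fruit counts × single-fruit weight) / sampling area`.
α is rounded to two decimals only for reporting (matching published
tables); internal computation keeps full precision, and under a uniform
multiplicative model bias the full-precision correction recovers the true
orchard yield exactly.  The method assumes the sampled trees are
representative of the orchard; a single scalar cannot express spatially or
temporally varying bias.

## Synthetic data

The county-year generator emulates the structure of the study region:
22 counties × 5 seasons by default, per-channel seasonal bumps
(sin² over the 7-month window) with per-county phase, per-record amplitude
U(0.5, 1.5), and a per-county vegetation-vigor multiplier U(0.8, 1.2).
Channel bases/amplitudes sit in plausible native units (reflectances ~0.1,
soil moisture ~0.25 m³/m³, air temperature ~283 K, NDVI peaking ≤ 0.93).
Yield is the *documented linear model*
`intercept + Σ_c w_c·mean_t(channel_c) + w_area·area + ε`,
ε ~ N(0, noise_sd²), with vegetation indices carrying most weight; the
defaults give yields of roughly 1250 ± 205 kg/mu over 820–1800, matching
the scale of published county statistics.  The default noise_sd of
10 kg/mu is ~5 % of the deterministic yield sd.  Because the model is
exactly linear in the channel means, ordinary least squares on the
generated features recovers the weights to machine precision at zero
noise — the oracle used by the recovery tests.

The generator does **not** emulate spatial structure, cloud contamination,
inter-annual climate trends, label-noise heteroscedasticity or any
nonlinear yield response.  Passing recovery tests therefore demonstrates
that the pipeline can extract a known signal under realistic dimensions
and noise — not that it attains any particular accuracy on real data.

Recovery experiments use 60 county-years (12 counties × 5 seasons, the
test season held out, ~38 training records before augmentation) — a size
chosen so a 20-seed replication completes in minutes on one CPU core while
keeping the per-seed sample regime as hard as the real setting.

## Known limitations

* The autodiff engine is float64/CPU and favors clarity over speed; at
  production image scales a framework-based reimplementation of the blocks
  would be needed.
* SS2D is non-selective (no input-dependent state transition).
* The VAE treats categorical codes continuously.
* Year embeddings cannot extrapolate a year effect to unseen years (they
  are zero-initialized to stay neutral); the synthetic generator has no
  year effect, and real cross-year transfer should be validated before
  trusting it.
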