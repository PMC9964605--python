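# Methods

## Features

A trial (channels × time, microvolts) is cut into non-overlapping windows
(default 1 s); a partial trailing window is discarded.  Each window is
Hamming-tapered, and the periodogram PSD is integrated over each band —
δ 1–3, θ 4–7, α 8–13, β 14–30, γ 31–50 Hz, half-open frequency bins
`[lo, hi)` so the integrated width equals `hi − lo` at 1-Hz resolution.
The result is the *band variance* (the PSD feature); for a white signal of
variance v it is ≈ `v·(hi−lo)/(fs/2)`.  The differential-entropy feature
is the Gaussian entropy of that variance,

    DE = ½ ln(2πe σ²)   (natural log, nats),

the standard band feature for this task.  The natural-log base is chosen
because the Gaussian-entropy derivation is exp-based; no published source
for this pipeline states the base, so nats are used consistently (any
fixed base only rescales features linearly).  Variances are clamped at
1e-8 before the log.

Trials are right-zero-padded to a fixed window count (default 265, the
convention for the public 62-channel corpus this mirrors); longer trials
are truncated from the end.  Padding happens *before* per-subject
standardization: each (channel, band, window) feature is centered and
scaled to unit population variance within each subject's trials
(ε-guard 1e-8; constant features map to 0).  Because every subject is
normalized against itself only, the transform introduces no leakage
across LOSO folds and can be applied once up front.

Channel presets: `seed12` = FT7, T7, TP7, P7, C5, CP5, FT8, T8, TP8, P8,
C6, CP6 — the temporal-area subset known to carry most emotion signal.
Band presets: `four` = θ,α,β,γ; `all` adds δ.

## Electrode graph

Electrode positions come from an idealized spherical 10-10 montage
generated in-package (midline at 18° steps, temporal ring at 72° from the
vertex, lateral rows by great-circle interpolation; CB1/CB2 below the
parieto-occipital ring).  Distance units are then fixed once by a
geometric calibration: coordinates are rescaled so the 0.2 quantile of
squared inter-electrode distances equals δ = 5, making ~20% of entries of

    A_ij = min(1, δ/d_ij²),  A_ii = 1

saturate at 1 — the stated design property of this initialization.  The
calibration is purely geometric and precedes any learning.

Nine homologous left–right pairs (FP1–FP2, AF3–AF4, F5–F6, FC5–FC6,
C5–C6, CP5–CP6, P5–P6, PO5–PO6, O1–O2) are set to −1, following the
convention that a negative initial weight lets the network express
differential (asymmetry) information; pairs absent from a channel subset
are skipped (the 12-channel set keeps C5–C6 and CP5–CP6).

Propagation uses `S = D̃^{-1/2} Ã D̃^{-1/2}` with `Ã = A + I` taken
literally (so the initial effective diagonal is 2) and **absolute-value
degrees** `D̃_ii = Σ_j |Ã_ij|`: global connections and learning make `A`
signed, and the absolute degree keeps `D̃^{-1/2}` real.  `S` is recomputed
from the current `A` on every forward pass; `A` is the trained parameter.

## Network

Per band b: `H_b = ReLU(S_b (S_b X_b Θ₁) Θ₂)` — two propagation steps,
no intermediate nonlinearity (the "simplified" convolution collapses
powers of S and linear maps), hidden width h1 = 128 (unspecified
upstream; configurable), output width fixed at 64 so each electrode's
embedding folds row-major into an 8×8 map.  Electrodes then act as
convolution channels through:

| stage | kernel/stride | output |
|---|---|---|
| conv1 | 2 / 1 | (N, out1, 7, 7) |
| SRM1  | – | (N, out1, 7, 7) |
| conv2 | 2 / 1 | (N, out2, 6, 6) |
| SRM2  | – | (N, out2, 6, 6) |
| conv3 | 2 / 1, pad (0,1)×(0,1) | (N, out3, 6, 6) |
| maxpool | 2 / 2 | (N, out3, 3, 3) |

out1/out2/out3 = 128/256/8 for 62 channels, 32/64/8 for 12; the flattened
band vector has length 72.  The printed stride column of the source table
cannot reproduce its own shape column for conv3 (6×6→6×6 needs padding)
or the pool (6×6→3×3 needs stride 2); the shape column is treated as
authoritative, hence the asymmetric padding and pool stride 2.

SRM: per conv channel, style = (mean, population std over the map,
ε = 1e-5 in the root); a per-channel bias-free linear map of the two
style moments, batch norm over channels (momentum 0.1, eps 1e-5), and a
sigmoid give a gate in (0,1) multiplied back onto the map.  A tiny affine
squeeze (`g·(1−2e−12)+1e−12`) keeps gates strictly inside the open
interval even where the sigmoid saturates in floating point.  `-SRM`
ablation makes both SRM stages identity.

Band vectors are fused as `Band_f = Σ W_i Band_i` with `W = softmax` of
free logits (initialized equal), guaranteeing the simplex constraint
`ΣW=1, W>0` throughout training; a single band degenerates to W = (1).
The "direct" mode instead concatenates all bands along the feature axis
into one shared encoder (the no-fusion baseline).  A linear layer and
softmax give 3-class probabilities (negative, neutral, positive).

Loss: `Φ = CE + a·Σ_b ‖A_b‖₁`, a = 0.01 by default (grid
{1, 0.1, 0.01, 0.001} exposed).  All parameters — including every A_b and
the fusion logits — take the same Adam step; `freeze_adjacency`
reproduces the fixed-graph ("NA") control in which A_b never changes.

## Training protocol

LOSO over subjects in sorted order; Adam (β = 0.9/0.999, no weight
decay), lr `0.001·0.96^epoch` — the decay factor is not specified
upstream, 0.96 keeps the final lr at ~13% of lr0 over 50 epochs — batch
64, shuffled per epoch with the run seed; a trailing batch of size 1 is
skipped because batch norm needs ≥ 2 samples in training mode.  Fold
accuracy = mean test accuracy of the last 10 epochs; the confusion matrix
uses final-epoch predictions.  Run summary: mean and *population* STD
over folds, and the row-normalized aggregate confusion in percent.

## Numerical core

The network runs on an in-package reverse-mode autodiff tape over NumPy
(BLAS matmuls; convolutions as one GEMM per 2×2 kernel tap).  Default
parameter dtype is float32 for speed; gradient-check tests run the same
code in float64 and compare every parameter family's analytic gradient to
central finite differences at 1e-4 relative tolerance.  Weight
initialization is uniform fan-in; all randomness (init, batching,
generators) flows from explicit integer seeds through
`numpy.random.default_rng`, giving bit-identical reruns.

## Synthetic world

The DE generator plants: class-specific mean elevations (effect size
1.5) on disjoint sets of 4 (band, channel) pairs per class; iid Gaussian
window noise (sd 1.0); per-subject offsets (sd 0.3) constant over
windows, mimicking the inter-subject shift that per-subject normalization
removes; and one graph-diffusion step through the geometric `S` of the
true montage, inducing spatially correlated channels.  Defaults: 6
subjects × 20 trials/class, 12 channels, 4 bands, 32 windows — large
enough to train the full model on CPU in minutes, small enough for CI.
Class-conditional distributions are Gaussian with shared covariance, so
the Bayes rule is linear and its Monte-Carlo accuracy
(`bayes_reference_accuracy`) is an exact ceiling; a fitted linear
discriminant on a large draw cross-checks it in the tests.  The raw
generator emits sums of band-limited Gaussian noise whose amplitude
doubles on active pairs (a DE elevation of exactly ln 2), exercising the
featurizer end to end.

What a green synthetic run establishes: the pipeline recovers plantable
linear-Gaussian band/channel structure across held-out subjects, at the
stated sizes, and collapses to chance when the effect is removed.  What
it does not establish: performance on real EEG (nonstationarity, 1/f
spectra, artifacts, nonlinear class structure are all absent), or the
published accuracy figures on the access-restricted 62-channel corpus,
which cannot be reproduced without that data.

## Known limitations

- No artifact handling, re-referencing or ICA; featurization starts at
  band power, matching the provider-extracted-feature setting.
- The NumPy core is single-threaded except for BLAS; large (62-channel,
  265-window) configurations train slowly relative to GPU frameworks.
- The idealized spherical montage approximates, not measures, electrode
  geometry; the δ-calibration property, not absolute distances, is what
  downstream code relies on.
- Batch norm makes training-mode forward passes batch-dependent;
  evaluation uses running statistics and is deterministic.
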