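# Methods

## Problem

Central aortic pressure (CAP) — the pressure at the proximal aorta — tracks
cardiovascular risk more closely than peripheral pressure, but measuring it
directly requires catheterization. `capwave` estimates the full CAP waveform
non-invasively from a single-channel radial artery pressure waveform
(applanation tonometry, 128 Hz), treating the task as causal
sequence-to-sequence regression: the estimate at sample *n* uses only radial
samples 0..*n*.

## Model

The estimator is a temporal convolutional network (TCN) with an attention
stage in every residual block.

**Causal dilated convolution.** Each convolution computes
F(n) = Σᵢ f(i)·x(n − d·i) with dilation d = 2ˡ at level *l*, implemented by
padding p = (k−1)·d zeros and chomping the trailing p samples, so every
layer preserves length and strict causality. The receptive field of an
L-level stack is R = 1 + (k−1)(2ᴸ − 1); `min_layers(N, k)` returns the
smallest L whose receptive field covers an input of length N. Running a
model whose receptive field is shorter than the input is legal and merely
logs a warning — outputs then use at most the last R samples of history.

**Residual block.** Two weight-normalized causal convolutions, each
followed by ReLU and dropout, then the attention stage; the skip path is
the identity, or a 1×1 convolution when channel counts differ; a final ReLU
follows the sum. Weight normalization reparameterizes each output-channel
filter as w = g·v/‖v‖ with g initialized to ‖v‖.

**Attention.** Two variants, selected by configuration:

* `channel` (default): squeeze-and-excitation gating. The squeeze is a
  *running* time average m(n) = mean(z[:, :n+1]) rather than a whole-record
  average, so the gate at time n — sigmoid(W₂ relu(W₁ m(n) + b₁) + b₂),
  bottleneck width C/reduction (min 1) — depends only on the past and the
  block stays causal. The running mean also gives the network access to
  record-level amplitude statistics, which is exactly what the calibration
  part of this task needs (see the comparison example: without gating the
  plain TCN is much worse at pressure-level calibration).
* `temporal`: scaled dot-product self-attention over time with a causal
  mask (position n attends to j ≤ n). O(N²); provided for experimentation.
* `none` reduces the architecture exactly to the baseline TCN used in the
  model comparison.

**Head.** A 1×1 convolution maps the last level's channels to the scalar
pressure output.

**Implementation.** The network is pure NumPy (float64, one record at a
time) with hand-written reverse-mode gradients for every layer, verified
against central finite differences in the test suite (tolerance ~5e−7 per
parameter). Initialization is He-scaled per layer by default (a fixed SD is
available via `init_sd`; very small fixed SDs such as 0.01 noticeably slow
optimization in this depth range). Dropout is disabled at inference.

## Training

Records are normalized with the fixed global min-max map x̃ = (x − 45)/135
(constants in mmHg, shared by inputs and targets, inverted exactly for
reporting); the four per-sequence normalizations (min-max, z-score with
population SD, mean normalization, unit L2 norm) are library functions kept
for comparison, since per-sequence statistics make them non-invertible
across a dataset. The dataset is split 70/30 by seeded shuffle (train size
= round(n·fraction)); the test split is never used for tuning. The loss is
the MSE L = (1/N) Σ (yₙ − ŷₙ)², minimized with Adam; each mini-batch
averages per-record gradients before one step. Runs are deterministic given
the model seed (init, dropout) and training seed (shuffling) on a fixed
BLAS configuration.

Defaults: k = 2, 7 levels (receptive field 128 samples = one cardiac cycle
at 60 bpm), 16 channels, dropout 0.2, channel attention with reduction 4,
lr 1e−3, batch 16. The receptive-field-coverage rule (L = `min_layers`)
would give 10 levels for a 1024-sample record; one-cycle memory is used
instead because the synthetic records are beat-periodic and the smaller
stack trains comfortably on a single CPU. For the reported regression
experiments a slightly larger setting is used: 32 channels, dropout 0
(regularization hurts on this noise-dominated, data-rich task), batch 4,
and a staged learning-rate schedule 3e−3 / 1e−3 / 3e−4 / 1e−4 over ~85
epochs (~7 minutes on one CPU for 300 records).

## Synthetic cohort generator

The measurement cohort behind this method is not public, so the package
ships a generator whose *defaults are the published cohort statistics*:

| quantity | mean ± SD | range |
|---|---|---|
| heart rate (bpm) | 67.5 ± 9.8 | truncated to [40, 120] |
| radial SBP (mmHg) | 119.8 ± 15.0 | truncated to [80, 200] |
| radial DBP (mmHg) | 75.1 ± 9.8 | truncated to [40, 110], DBP < SBP − 20 |
| rSBP − aSBP (mmHg) | 14.59 ± 5.95 | [0, 43] |
| aDBP − rDBP (mmHg) | 1.40 ± 1.02 | [0.20, 14] |

Sampling details that matter:

* **Moment-matched truncation.** Each truncated normal's location parameter
  is solved (Brent root finding) so the *truncated* distribution has the
  stated mean. Without this the hard bounds bias the realized means — most
  visibly the diastolic difference, whose naive truncated mean would be
  ~1.63 instead of 1.40. Realized SDs are slightly below nominal, a known
  and accepted property of truncation.
* **SBP–DBP correlation.** DBP is drawn conditionally on SBP with
  correlation ρ = 0.7 (physiologic; the published table gives only
  marginals, which are preserved). This keeps the DBP < SBP − 20 constraint
  rarely binding; the constraint is enforced by truncating the conditional
  DBP distribution, leaving the SBP marginal exact, and the conditional
  location is calibrated by numerical integration over the SBP distribution
  so the DBP marginal mean is exact too.
* **Aortic ordering.** The amplification pair (Δsbp, Δdbp) is redrawn until
  aortic pulse pressure ≥ 1 mmHg (rare; residual bias on the Δsbp mean is
  ~0.1 mmHg, well inside sampling error at the tested cohort size).
* **Beat morphology.** One template per subject: half-cosine systolic
  upstroke from 0 (end-diastole) to an exact peak at `peak_time`
  (U[0.25, 0.35] of the beat), exponential diastolic decay with constant
  `decay_tau` (U[0.12, 0.22]), and a Gaussian dicrotic bump; rescaled so
  min = 0 and max = 1 exactly. The piecewise form guarantees the dominant
  peak sits in the first 40% of the beat and that zero dicrotic amplitude
  yields a single local maximum.
* **Forward channel.** The radial waveform is the aortic record passed
  through a single-tube transmission (tube-load) model
  H(ω) = (1+Γ)e^(−iωτ) / (1 + Γe^(−2iωτ)) with reflection coefficient
  Γ ~ U[0.3, 0.7] and delay τ ~ U[0.03, 0.06] s, applied per record via the
  FFT (records are beat-periodic by construction: an integer number of
  identical beats of duration 60/HR s). This is the simplest physical model
  that produces the pulse-pressure amplification phenomenon.
* **Calibration and noise.** The aortic waveform is aDBP + (aSBP−aDBP)·shape
  exactly; the radial waveform is affinely rescaled so its extrema equal the
  sampled radial SBP/DBP exactly. Additive Gaussian measurement noise
  (default SD 0.5 mmHg, configurable) is applied afterwards, so stored
  subject parameters always describe the noise-free waveforms.

**What the generator does and does not emulate.** It reproduces the cohort's
marginal statistics, the amplification phenomenon, and plausible beat
morphology; it does *not* reproduce individual measured waveforms, beat-to-
beat variability within a record, respiratory modulation, or pathology.
Consequently, passing the end-to-end tests shows the pipeline learns an
invertible hemodynamic channel at realistic SNR — not that it reaches any
particular accuracy on clinical data.

**An identifiability property worth knowing.** The amplification draw Δsbp
is independent of the tube parameters, and the radial waveform is exactly
recalibrated afterwards, so the amplification magnitude leaves no trace in
the model input: its spread enters the error of *any* predictor. A
shape-oracle predictor (true aortic shape, optimal population calibration)
still incurs ≈ 2.1 mmHg held-out waveform MAE under the defaults, and
per-record SBP errors cannot beat ≈ 5.4 mmHg on average. The trained model
approaches these floors (≈ 2.5 mmHg waveform MAE at 300 training records);
published results on real cohorts are much lower partly because there the
reference CAP is itself derived from the radial recording, making the
target far more predictable from the input.

## Evaluation

Per record: waveform MAE, RMSE, MAX error, and Spearman's rank correlation
(average ranks for ties, computed as the Pearson correlation of the rank
vectors, identical to 1 − 6Σd²/(N(N²−1)) in the tie-free case; the SCC of
a constant sequence is undefined and reported as NaN by the metric bundle).
Point features: SBP = waveform max, DBP = min, MAP = time average (a
DBP + PP/3 estimator is available as an option). For scalar features the
per-record MAE, RMSE, and MAX all equal the absolute error, so those table
columns coincide by construction. Aggregation is mean ± SD of per-record
values over the test set; SCC is aggregated as the mean of per-record
coefficients. Two models are compared with a classical paired t-test on
per-record errors (df = n−1, two-sided), annotated * (p < 0.05),
** (p < 0.01), or n.s.; identical models produce zero-variance differences
and are annotated n.s. by contract. The alternative reading of the
comparison — testing estimated-versus-measured pressures per model rather
than model-versus-model errors — is not implemented.

## Numerical choices and degenerate inputs

* All sequence math is float64; the affine normalization round-trip is
  exact to 1e−12 and the simulator's calibration to 1e−9.
* Constant sequences are rejected by min-max/mean/z-score normalization,
  the zero sequence by unit-norm scaling; zero-variance differences make
  the paired t-test degenerate; all raise typed errors.
* Weight-norm divisions guard with a 1e−12 epsilon; the softmax in
  temporal attention is max-shifted row-wise.
* Early stopping (off by default) uses a relative improvement threshold of
  1e−6 on the epoch training loss.
* Truncated-normal draws use inverse-CDF sampling (one uniform per draw),
  making subject sampling exactly reproducible from the generator seed.

## Problem sizes used by the shipped tests

Simulator calibration uses 2000 subjects (means checked within 3 standard
errors). The capacity check overfits one record (~1100 samples) to
MSE < 1e−3 in 2000 steps; the generalization experiment trains on 300
records and evaluates on 100 held-out records (criterion: mean per-record
waveform MAE < 3 mmHg), with the staged schedule above. These sizes were
chosen as the smallest that make the statistical checks meaningful.

## Known limitations

* Whole-record training assumes records of a (per-record) fixed length;
  variable-length batching with padding/masking is not implemented.
* The temporal attention variant is O(N²) and impractical to train on long
  records in this NumPy implementation.
* No GPU path, no multi-lead inputs, no recurrent baselines.
* Bitwise determinism holds for a fixed BLAS/threading configuration;
  across different BLAS builds results agree only to floating-point
  reduction order.
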