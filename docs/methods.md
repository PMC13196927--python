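# Methods

## The reconstruction model

The task is posed as masked-signal generation. A 12-lead segment
`x ∈ R^{12×T}` (canonical lead order I, II, III, aVR, aVL, aVF, V1–V6) is
multiplied by `(1 − M)`, where the binary mask `M` is zero on the retained
leads and one elsewhere; the default retains II, V1, V5, and presets exist
for I/II/V3 and I-only. The model always sees a 12-channel tensor with
zeroed rows — not a 3-channel tensor — so the same architecture serves any
retained subset.

**Encoder.** An initial convolution projects 12 channels to `base_channels`
(128 at study scale). Each of `n_down_stages` = 3 stages applies
`residual_blocks_per_stage` = 2 residual blocks
(conv–groupnorm–SiLU–conv–groupnorm plus identity skip) followed by a
stride-2 convolution that halves the time axis and widens channels along a
geometric plan toward `bottleneck_channels` (512 at study scale). Two
parallel 1×1 convolution heads emit the posterior parameters
`μ, log σ² ∈ R^{T′×d}` with `T′ = T/8` and latent width `d = 4`.
`log σ²` is clamped to [−30, 20] against overflow; head biases start at 0.

**Latent.** `z = μ + σ ⊙ ε`, `ε ~ N(0, I)` (reparameterization, so the
sampling step is differentiable). At inference the posterior mean is used
unless a seed explicitly requests a stochastic draw.

**Decoder.** Mirrors the encoder: a 1×1 projection from `d` to the
bottleneck width, a residual block, then — at the lowest resolution only —
a pre-normalized multi-head self-attention block over the time axis
(4 heads) with a residual connection, followed by per-stage nearest-neighbor
upsampling (×2), a channel-narrowing convolution and residual blocks, and a
final groupnorm–SiLU–conv back to 12 channels.

**Loss.** `L = L_recon + β·KL` with β = 1e-4. `L_recon` is the
*per-element* mean squared error; a `sum_per_sample` switch provides the
per-sample squared-norm variant, but the per-element form is the default so
that β keeps the same meaning across segment lengths. The KL term uses the
closed form `−½ Σ_j (1 + log σ_j² − μ_j² − σ_j²)`, summed over the `d`
latent coordinates and averaged over batch and time positions; a unit test
pins it against a 10⁶-sample Monte-Carlo estimate. An optional perceptual
term (mean squared difference of features from any deterministic embedder)
can be added with its own weight; it is off by default.

**Lengths.** Strided downsampling requires `T` divisible by 8. The
`reconstruct` helper symmetric-edge-pads the time axis to the next multiple
and crops after decoding; default 2-second segments (500 samples at 250 Hz
or 1000 at 500 Hz) pad to 512/1024.

All neural computation runs on a small in-repo numpy reverse-mode autodiff
engine (`ecgrecon.nn`). Its operator set is exactly what the models need;
analytic gradients of the full objective are verified against central
differences to 1e-4 relative error in the test suite.

## Training regime

AdamW (decoupled weight decay, default coefficient 1e-2) with a cosine
OneCycle schedule: warm-up from `lr_init` to `lr_max` over 20% of total
steps, cosine annealing to a terminal rate of `lr_max/1e4`. Study-scale
defaults are `lr_init` = 1e-5, `lr_max` = 5e-5, batch 16, 10 epochs,
checkpoint per epoch. Gradient clipping and mixed precision are available
as flags but off by default (full fp32 for reproducibility; model math is
float32, gradient checks run in float64). Train/validation sets must have
disjoint subject sets — the trainer raises rather than assumes. An
early-stopping hook exists but is disabled by default; validation MSE is
recorded each epoch and never used for selection.

**Desk-scale configuration.** The package's reference experiments
(`ecgrecon.experiments`) train a small model (base 32, bottleneck 64,
d = 4) on 200 two-second segments at 250 Hz — about 130 optimizer steps.
The study-scale learning rates are tuned to very large record counts and
barely move a fresh model in 130 steps, so the desk runs keep the OneCycle
shape and all other hyperparameters but use a conventional small-data Adam
scale: `lr_init` = 3e-4, `lr_max` = 3e-3. Problem sizes: the training study
uses 50 subjects × 4 segments (held-out fraction 0.2); the probe study uses
100 subjects × 4 segments (held-out fraction 0.3).

## The synthetic generator

The generator exists so every claim in the package is testable without any
data download, and it is built to make the task's geometric assumptions
*exactly* true:

- Cardiac activity is a 3-D dipole: five Gaussian bumps in cardiac phase
  (P, Q, R, S, T), each with a 3-vector amplitude in millivolts, a phase
  width and a center; per-beat RR intervals are drawn from the subject's
  heart-rate distribution (default mean ~N(70, 8) bpm clipped to [45, 110],
  SD ~|N(2, 1)| bpm), and per-subject morphology jitters the base waves
  (±15% amplitudes, ±10% widths, small center shifts with strictly
  increasing order preserved).
- Leads are linear projections through a 12×3 matrix whose limb rows sit at
  the classical hexaxial angles (I at 0°, II at +60°), whose augmented rows
  follow Goldberger's definitions exactly, and whose precordial rows are
  fixed unit vectors fanning across the horizontal plane (V1 at 120° from
  leftward toward anterior, down to V6 at 0°). Consequences used as test
  oracles: noise-free 12×T output has numerical rank 3; I + III = II and
  aVR + aVL + aVF = 0 hold to float precision; the {II, V1, V5} submatrix
  has rank 3, so a linear reconstructor is exact on clean data.
- Condition labels are explicit morphology edits with deterministic phase
  windows derived from the subject's wave parameters (ST window: from
  S-center + 2 widths to T-center − 1.5 widths): ST-segment offset (mV,
  declared leads), T-wave inversion (scaling within the T window),
  frontal-plane axis rotation (degrees, applied in dipole space), and PR
  shortening (ms, the P window shifted toward the QRS). Magnitude 0 is an
  exact no-op for every kind.
- Noise: sinusoidal baseline wander (default 0.08 mV at 0.33 Hz), white
  broadband (0.02 mV SD), powerline sinusoid (0.02 mV at 50 Hz), and
  contiguous NaN bursts (default probability 0.1 per record, 25 samples) —
  contiguous rather than i.i.d. dropout so neighborhood imputation is
  exercised nontrivially. An all-zero config returns the input bit-identical.

What the generator does *not* emulate: realistic torso volume-conductor
effects, arrhythmic rhythms beyond rate variability, electrode-motion
artifacts, or physiologically validated pathology morphology. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
reconstruction problem's linear-geometry core is handled exactly — not that
the model reaches any particular fidelity on real patients.

## Preprocessing choices

Imputation runs before Fourier resampling (spectral interpolation is
undefined on NaNs): each NaN takes the mean of finite samples within ±5
samples (configurable), falling back to the lead mean; an all-NaN lead is an
error naming the lead. Resampling is Fourier zero-pad/truncation
(`scipy.signal.resample`), per lead. Z-scoring is per record per lead with
eps = 1e-8, off by default for generation and on for the downstream probe.
Segmentation defaults to non-overlapping 2-second windows. Subject-grouped
splitting rounds the requested test fraction to a whole number of subjects
(clamped to leave both sides nonempty) and is deterministic in its seed.

## Evaluation

Per-lead reports score only the non-input leads by default (reconstructing
the leads you already have is trivial with retained-lead pass-through); a
flag scores all 12. The overall row is the pooled per-element aggregate of
the same lead subset, a tested invariant.

FID requires a feature embedder; the study-scale embedder (a large
pretrained ECG foundation network) is out of scope, so the interface is
pluggable with three in-package defaults — a seeded random-projection
embedder, the trained VAE encoder (pooled posterior means), and the
downstream backbone — and every report names the embedder used, because FID
values are only comparable within one embedder. The matrix square root in
the Fréchet formula is computed by symmetric eigendecomposition of
`Σ_a^{1/2} Σ_b Σ_a^{1/2}` with negative eigenvalues clipped at a −1e-6
tolerance (beyond it, a conditioning error is raised).

AUROC is the rank statistic (ties counted half, via scikit-learn), verified
exactly against an O(n²) pairwise oracle. The "optimal threshold" reported
per condition is the Youden-index maximizer (sensitivity + specificity − 1)
on the ROC curve. Confusion metrics with a zero denominator are reported as
NaN, never fabricated.

## The downstream probe

The backbone is a 1-D squeeze-and-excitation residual bottleneck network
(1×1 reduce, k×1, 1×1 expand convolutions, batch normalization, SiLU/Swish
activations, SAME padding, SE channel gating, stagewise downsampling,
global average pooling; default 3 stages of 16/32/64 channels, kernel 7).
It is pretrained briefly on real labelled synthetic 12-lead signals —
enough to give non-trivial features — then frozen (asserted by parameter
hash). The head is a single affine map trained with per-label sigmoid
binary cross-entropy by full-batch gradient descent on standardized
features, deterministic under its seed.

The ordering study compares three input arms on a lateral ST-elevation task
(0.2 mV on I, aVL, V5, V6, prevalence 0.5, plus an anterior T-inversion
label, mild noise): real 12-lead, VAE reconstruction, and single-lead-II
zero-fill. Reconstruction for the probe uses retained-lead pass-through
(decoder output only on dropped leads), the deployment-relevant variant.
Expected physics: the lateral ST signal flows through retained V5, so
reconstruction preserves it; lead II is not in the perturbed set, so the
single-lead arm is near chance; the anterior T-inversion label touches no
retained lead and is *not* recoverable from reconstruction — which is
exactly the failure mode reduced-lead systems have, and why the ordering is
checked on the ST label.

## Numerical and design notes

- Residual-block count, attention heads, group-norm groups, and the
  downsampling depth are free parameters of `ModelConfig`; the defaults
  (2 blocks/stage, 4 heads, 8 groups, 3 stages) are declared choices, not
  fitted ones.
- Checkpoints are `.npz` archives of all parameters and buffers in
  deterministic order with the model/training configs embedded as JSON;
  round trips are bit-exact and corrupt files raise a format error.
- The linear baseline pools all time samples across records, solves the
  normal equations (optional ridge), and by default passes retained leads
  through unchanged; a rank-deficient retained block with zero ridge is a
  conditioning error rather than a silent pseudo-inverse.
- Known limitations: the autodiff engine is single-device CPU float32/64
  and unoptimized for large models; the generator's pathology edits are
  schematic; FID magnitudes are embedder-relative; no statistical
  comparison machinery (bootstrap CIs, DeLong tests) is included.
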