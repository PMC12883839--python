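# Methods

`leafwp` estimates leaf water potential (Ψ_leaf, MPa, negative; more
negative = drier) from 176-band leaf reflectance spectra spanning
393.7–1001.4 nm. This note records the models, the defaults and why they
are what they are, the numerical choices, and what the bundled simulator
does and does not establish.

## The regression problem

Ψ_leaf datasets from dehydration experiments are small (a few hundred
paired measurements) and imbalanced: pressure-chamber measurements fail
increasingly often as leaves dry, so the strongly stressed end of the label
axis is thinly sampled, while it is exactly the region that matters for
drought monitoring. The pipeline attacks this on three fronts:
augmentation (a conditional GAN resamples the label axis evenly), feature
extraction (multi-scale convolution plus self-attention over wavelengths),
and the objective (label-distribution learning instead of bare pointwise
MSE).

## Reflectance calibration and normalization

Raw per-band intensities are calibrated against a white reference panel
and a dark frame, R_c = (I_o − I_d)/(I_w − I_d) · R_w. Negative calibrated
values (possible under sensor noise) are clipped to 0; values above 1 are
kept, since a leaf can out-reflect the panel at single bands. Spectra are
then normalized per spectrum (row-wise) by the maximum absolute value.
Whether normalization should be per spectrum or per band is genuinely open
in this setting; per spectrum is the common spectroscopy reading, is
independent of the train/test split (hence leak-free by construction), and
is the default, with per-band available via the `axis` argument. Labels
are held in MPa internally (1 MPa = 10 bar); the CSV reader accepts either
a `psi_mpa` or a `psi_bar` column and converts on load, which prevents
silent 10× unit errors.

## Synthetic campaigns

No public paired (spectrum, Ψ_leaf) dataset exists for this configuration,
so the package bundles a phenomenological simulator used by every test and
example. It is a template model, not radiative transfer: Ψ_leaf has no
established physical forward model, which is precisely why the regression
is learned.

* **Spectral template.** Low visible reflectance (~0.05–0.12) with a
  Gaussian chlorophyll absorption dip at 680 nm (width 25 nm), a logistic
  red-edge rise centered at 722 nm, and an NIR plateau at ~0.45.
* **Water-status effect.** The plateau rises linearly with stress:
  `nir_sensitivity` = 0.08 reflectance units per MPa of Ψ decline, so the
  noiseless Ψ→spectrum map is injective and the task well-posed. No
  quantitative reflectance–Ψ slope is available for this configuration;
  0.08 was chosen once so that a linear baseline is good but imperfect,
  leaving measurable headroom for the deep model, and is not revisited.
* **Label imbalance.** Ψ = hi − (hi−lo)·Beta(1.8, 3.0) on
  [−2.5, −0.1] MPa, giving mean −1.0 MPa with density thinning toward
  −2.5 MPa — the skew a slow-dehydration campaign produces.
* **Noise.** Per-spectrum multiplicative gain (SD 0.02) then per-band
  additive sensor noise (SD 0.005), clipped to [0, 1.2].

What passing tests on this simulator shows: the pipeline recovers a smooth
injective spectral response under realistic imbalance and noise, the
components interact as designed, and the protocol is leak-free and
reproducible. What it does not show: performance on real leaves, where
structural variation between leaves, water-band absorption features,
instrument drift and illumination geometry produce effects no smooth
template captures.

## Conditional GAN augmentation

Generator and discriminator are small fully connected stacks over 176-dim
vectors (G: 16-dim noise + condition → 128 → 128 → 176; D: spectrum +
condition → 128 → 64 → 1), with the Ψ condition normalized to [−1, 1] and
concatenated to both inputs. Training follows the conditional min–max
game; the generator step uses the non-saturating variant. Defaults: Adam
(lr 1e-4, β₁ = 0.5), batch 32, 3000 epochs, seeded.

Two choices matter in practice:

* **Generator weight averaging.** Samples are drawn from an exponential
  moving average of the generator weights (decay 0.999). The adversarial
  game oscillates around its equilibrium; averaging removes most of that
  oscillation and improved mean-spectrum fidelity by an order of magnitude
  (SAM ≈ 0.2 rad → ≈ 0.01 rad) in development runs.
* **Even condition grid.** The 500 augmentation conditions are evenly
  spaced over the training Ψ range rather than drawn uniformly at random:
  the point of augmentation is gap-filling coverage of the sparse dry end,
  which an even grid guarantees.

Fidelity is monitored as the spectral angle (SAM) between the mean real
and mean generated spectrum; angles below 0.1 rad are conventionally read
as high spectral fidelity. Mode collapse is acknowledged and monitored
(condition-responsiveness checks) but not countered beyond seeding and
EMA. Generated rows carry their conditioning Ψ as regression label.

## Feature extractor

A 1-D Inception-ResNet-style backbone: input batch norm → stem convolution
(1→8 channels, kernel 3, batch norm) → three parallel branches with
kernels 3/5/7 → channel concatenation → 1×1 fusion convolution (batch
norm) → residual addition with the stem → ReLU → flatten (8 × 176 = 1408
features). The two larger-kernel branches use the dual-path block; which
branches to convert is not prescribed anywhere, and the long-range
attention path is most useful where the convolutional receptive field is
already large, so kernel-5 and kernel-7 branches are the default
(configurable per branch).

The dual-path block computes, in parallel, a depthwise-separable
convolution path (1×1 → depthwise k → 1×1) and a single-head dot-product
self-attention path over the 176 positions (1×1 Q/K/V projections, scores
scaled by √d, plus a learnable L×L positional-encoding table added to the
scores), fused as α·attention + β·convolution with learnable scalars
initialized at 1. One attention head is the default because the sequence
is short; the head count is configurable. The depth — one stem plus one
three-branch stage — is deliberately shallow: a few hundred training
samples cannot support more.

Batch norm placement deserves a note: with batch norm only at the input,
the flattened features carry large constant offsets with tiny per-feature
variances, and SGD at the protocol's learning rate either diverges or
converges to the mean predictor (both observed in development). Batch norm
after the stem and fusion convolutions, plus a feature-wise batch norm at
the head input, condition the problem so the stated optimizer settings
work as given. Running statistics are re-estimated with one full pass
after training so inference is deterministic.

## Distribution-aware head

The label axis [min train Ψ − 3σ, max train Ψ + 3σ] is cut into k
intervals of length l (k = ⌈range/l⌉, centers l_j); a target y is encoded
as a Gaussian kernel of width σ evaluated at the centers and renormalized
(the continuous density does not sum to 1 on a discrete grid, and the KL
objective needs probability vectors). The head (feature batch norm →
1408 → 64 ReLU, dropout 0.2 → k, softmax) emits p̂; the prediction is the
decoded expectation ŷ = Σ p̂_j l_j, necessarily inside the grid. The loss
is

  L_total = C · mean_i (y_i − ŷ_i)² + mean_i Σ_j p_ij ln(p_ij/p̂_ij) + η Σ θ²

with defaults σ = 0.4 MPa, l = 0.15 MPa, C = 1, η = 1e-6, and p̂ clamped
at ε = 1e-12 inside the logarithm. σ, l and C are interpreted on the MPa
scale: with the default simulator ranges this yields ≈ 32 bins for 160
training rows, a sensible bin-to-sample ratio, whereas a bar-scale reading
would give over 150 bins. The MSE term is kept because the discrete
expectation is biased near the grid edges (the encode/decode round trip is
bounded by l/2 but not zero); C trades that correction against
distribution matching. The point-head variant (plain MSE regression) is
retained for ablation. No additional per-sample reweighting of the KL term
is applied; the regression coefficient C is the only balance knob.

## Evaluation protocol

Ten repetitions of a seeded 70/10/20 train/validation/test shuffle (floor
rounding for train and validation, remainder to test: 160/22/47 at
n = 229). Per repetition: optional GAN training and augmentation on the
training rows only, label grid from training labels only, SGD with
momentum 0.9, batch 256 (one full batch when the training set is smaller),
initial learning rate 0.05 decayed ×0.1 every 100 epochs with floor 1e-9,
dropout 0.2 on fully connected layers, He initialization for
convolutional and Glorot for fully connected weights, gradient
global-norm clipping at 5 (numerical safety at the stated learning rate),
no early stopping; the final-epoch model is evaluated. Default 300 epochs;
tests and examples use reduced counts (20–120) chosen for desk-scale runs,
stated per run.

Metrics per split: R², RMSE, MAE, RPD = SD(y, ddof 1)/RMSE, RPIQ =
IQR(y)/RMSE with linear-interpolation quartiles. Aggregation over
repetitions is mean ± SD; the ratio family is reported under two
conventions, both documented because both are in circulation: SDR as the
mean of per-split SD/RMSE ratios, and a pooled RPD as mean SD divided by
the RMSE pooled from all test residuals. Perfect predictions make the
ratio metrics infinite and are flagged as such rather than clamped.

Hyperparameter searches follow the protocol: a 5×5 grid over
σ ∈ {0.1…0.5}, l ∈ {0.05…0.25} at C = 1 scored by mean validation R²,
then a sweep over C ∈ {0…6} at the selected (σ, l). Validation always
uses raw (non-augmented) rows. The ablation harness evaluates all eight
on/off combinations of {GAN augmentation, dual-path blocks, distribution
head} on identical splits.

## Numerical and engineering choices

* All tensors are float64; the autodiff engine in `leafwp.nn` implements
  exactly the op set the networks need and is verified against central
  differences in the test suite.
* Softmax and the Gaussian encoder are computed with max-shift
  stabilization; KL uses 0·ln(0/·) := 0 and an ε-clamp on p̂.
* Determinism: every stochastic step (splits, GAN, init, minibatch order,
  noise draws) derives from explicit numpy Generators; a global seed
  expands as `component_base + split_seed + fixed offset`, so single
  repetitions reproduce in isolation.
* Degenerate inputs fail loudly: zero spectra in normalization or SAM,
  zero reference variance in R², zero white−dark denominator (reported
  with the band index), oversized GAN batches, unnormalized distributions
  in the decoder.

## Known limitations

The simulator's smooth template makes the task easier than real leaf
optics; absolute metric values on it say nothing about field performance.
The GAN's condition-responsiveness is modest (the mean spectral shape is
learned well; per-condition detail less so), consistent with the known
mode-collapse tendency of conditional GANs at this data scale. The
extractor and head sizes are sized for hundreds of samples and would need
rescaling for larger campaigns. Only 1-D spectra are handled; image cubes,
segmentation and ROI averaging are out of scope.
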