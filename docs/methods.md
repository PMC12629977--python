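# Methods

`celldiff` implements generative classification of single-cell images with
a class-conditional diffusion model, together with the evaluation apparatus
that such a classifier makes possible: generative anomaly detection,
counterfactual heat maps, and Bayesian psychometric analysis of confidence.
This note records the model, the design decisions, the defaults and their
rationale, and what the synthetic benchmark does and does not demonstrate.

## The diffusion classifier

### Forward process and denoiser

The forward process is the standard discrete variance-preserving diffusion

    z_t = sqrt(ab_t) z_0 + sqrt(1 - ab_t) eps,    eps ~ N(0, I),

with `ab_t = prod_{s<=t}(1 - beta_s)`, `ab_0 = 1`, and a linear beta
schedule whose endpoints (1e-4, 0.02 at T = 1000) are rescaled by 1000/T so
the total injected noise is comparable at any T. Default T = 400. The
model runs in pixel space through an identity codec at 32x32x3; the codec
is a pluggable contract (`encode`/`decode`/`latent_shape`), so a learned
autoencoder latent space can be substituted without touching classifier
code. The identity codec round-trips bit-exactly; any lossy codec must
report its reconstruction error.

The reference noise predictor `eps_theta(z_t, t, c)` is a small
convolutional encoder-decoder (~0.1 M parameters): one full-resolution
3x3 conv, two stride-2 downsamplings to 8x8, a bottleneck conv,
nearest-neighbour upsampling with additive skip connections, sinusoidal
timestep embeddings and one-hot class conditioning injected as per-channel
biases at every level.  The last decoder conv runs at half resolution and
upsamples afterwards — a full-resolution 3x3 there would dominate
inference cost while the final output conv still refines at full
resolution over the first-layer skip. Two gated structured output paths are added:

* a skip `g(t) * z_t`, which supplies the high-noise identity
  `eps ~ z_t` for free, and
* a class-template path `s(t) * M[c]`, one learned latent template per
  class with a learned timestep gate.

The template path matters. For a class approximated as a Gaussian with
mean `m_c`, the minimum-MSE noise prediction is approximately
`z_t / sqrt(1-ab) - sqrt(ab/(1-ab)) m_c` — precisely the span of the two
structured paths. Without it, a small network trained on visually distinct
classes converges to an essentially unconditional denoiser: it can infer
the class from `z_t` itself, the conditioning input receives no gradient
pressure, and the class-conditional error gap that classification depends
on collapses to zero. The template path gives the label direct gradient
flow; the conv stack then models spatially local, translation-equivariant
structure (granules, nuclear lobes) that a fully connected backbone
handles poorly. An MLP backbone with the same structured paths is kept as
a cheaper alternative (`arch="mlp"`), useful when model quality is not the
point.

All tensors are float32; gradients are hand-written (verified against
finite differences in the test suite) and optimised with Adam
(lr 2e-3, linear warm-up 100 steps, batch 32). Networks are trained for
4000 steps by default — a few CPU-minutes — inside the desk-scale band of
2,000–5,000 steps the benchmark is designed around. Half of the training
timesteps are drawn uniformly from {1..100} and half from {1..T}
(`low_t_frac = 0.5`): the class-conditional error gap the classifier reads
is concentrated at low noise levels, where mispredicting the class is
amplified by the 1/sqrt(1-ab) factor, so extra capacity is spent there.
Training is a pure function of its seed; every random draw in the package
flows through named Philox streams keyed on `(seed, operation, indices)`.

### Decision rule

Under Bayes' rule with a uniform class prior, the predicted class
maximises the class-conditional likelihood; the denoising loss is the
surrogate:

    c_hat = argmin_c E_{eps,t} [ w_t || eps - eps_theta(z_t, t, c) ||^2 ].

Each trial draws one `(t, eps)` pair and scores **every** surviving class
with that same pair, so between-class comparisons are paired and the
shared-noise component cancels. Two inference modes:

* **exhaustive** — a fixed number of trials, no elimination; the decision
  is the argmin of mean weighted errors (ties break to the lowest class
  index, logged);
* **eliminating** — successive elimination, the default: once every
  survivor has at least `min_evals = 20` scores, each non-best survivor is
  tested against the current best (lowest running mean) by a paired
  Student's t-test on the per-trial differences and eliminated when its
  mean difference is positive with p below 2e-3; inference stops at one
  survivor or 2000 trials.

The paired test is **two-sided** with a positive-mean direction guard.
With a one-sided test the performed test's statistic is effectively |t|
(only the currently-worse class is tested, and rejection implies the
observed ordering), so under the null the per-test false-elimination rate
doubles to ~2 alpha; the two-sided rule keeps it at the nominal level,
which the suite verifies by simulation (2000 identically distributed error
streams). Zero-variance paired differences get p = 0 when the mean is
positive (elimination certain) and p = 1 otherwise, which also pins the
degenerate-stream elimination time to exactly the 20th score. Sidedness is
config-exposed (`alternative`). Trials are *scored* in blocks of 16 for
throughput, but the test cadence is strictly per iteration and scores
drawn for a class beyond its elimination iteration are discarded, so block
size changes wall-clock only, not statistics (given the same RNG stream).

### Timestep weighting and range

`w_t` defaults to 1: with paired trials, any positive weighting is
unbiased for between-class comparison. The benchmark uses the optional
inverse-mean normaliser (`fit_timestep_weights`): mean across-class error
is estimated per timestep decile on the calibration split and `w_t` set to
its reciprocal. Unweighted means are dominated by low-t trials whose
absolute errors are large (order of the latent dimension) while the
informative *differences* are spread over all t; normalising equalises the
contribution per timestep and reduces decision variance. Inference may
also be restricted to a timestep band (`t_range`); the default is the full
range {1..T}.

### Confidence

The raw confidence of a decision is the gap between the two smallest
final mean errors (running means of all classes, including eliminated
ones — eliminated classes retain their scores up to elimination). The gap
is min-max rescaled to [0, 1] by a calibrator fitted on the validation
split and frozen before any test image is scored; applied values are
clipped. A discriminative baseline's confidence is the analogous top-logit
gap through the same calibration machinery.

## Anomaly detection

Images are scored with the same shared-trial machinery at a fixed 200
trials and no elimination (comparable error estimates for all classes are
needed). Two normality strategies:

* `min_error`: raw score = −min_c (mean weighted error). Simple and
  calibration-free, but confounded by per-image error scale: large or
  complex cells have larger absolute errors under *every* condition and
  can out-score genuine anomalies.
* `profile` (benchmark default): the K-vector of class-conditional mean
  errors is divided by its own mean — removing per-image scale — and the
  raw score is −min_c of the squared Mahalanobis distance of this profile
  to class c's profile distribution, estimated (mean and ridge-regularised
  covariance, ridge 1e-4) per class on up to 20 labelled validation images
  per class and frozen. In-distribution images produce profiles shaped like one of the
  known classes; anomalies produce profiles unlike all of them even when
  their absolute errors are unremarkable. On the synthetic benchmark this
  raises held-out-class AUC from the high 0.8s to ≈1.0.

Reported scores are min-max normalised over the combined evaluation batch.
Separation is summarised by the rank-statistic AUC (probability a random
abnormal image scores below a random normal one, ties half), sensitivity
and specificity at the Youden-optimal threshold, and kernel density curves
(Gaussian kernel, Silverman bandwidth, boundary reflection on [0, 1] so
each curve integrates to one; degenerate bandwidths fall back to 0.05).

## Counterfactual heat maps

Over N = 200 shared trials the signed residual mean
`Delta_c = (1/N) sum_n (eps_n - eps_theta(z_{t_n}, t_n, c))` is
accumulated per class from the same pass that fills the classifier's error
table. With `delta_c = Delta_c - Delta_chat` (so `delta_chat` is
identically zero) the decoded maps `H_c = decode(delta_c)` show what would
need to change for the image to be classified as c; under the identity
codec `H_c` is `delta_c` reshaped, bit-exact. The signed-mean accumulator
converges more slowly than scalar errors (no squaring, so trial noise
cancels only as 1/sqrt(N)), hence the larger default N. Maps are rendered
on a symmetric diverging scale centred at zero; overlays mark the pixels
whose channel 2-norm magnitude, after subtracting the per-map per-channel
median ("background"), lies in the top fraction q (default 0.1), ties
broken by scan order — a flat map marks nothing.

## Psychometric evaluation of confidence

An agent whose uncertainty is purely aleatoric behaves like an ideal
observer: accuracy as a function of a discriminability index x follows

    psi(x) = gamma + (1 - gamma - lambda) S(x; m, w),

with guess rate `gamma` fixed at 1/K and lapse rate `lambda` the
complement of the upper asymptote. The inner sigmoid S is a cumulative
normal re-parameterised so that S(m) = 0.8 (the threshold-at-80%-accuracy
convention, unscaled by guess and lapse rates) and S spans 0.05 to 0.95
over the width w (the standard psychometric-software convention; the
width definition is otherwise arbitrary and is isolated inside
`PsychometricModel`).

Fitting is exact-within-resolution Bayesian inference on a dense grid
(default 81 x 81 x 41 over m, w, lambda): Bernoulli likelihood pooled by
distinct signal level, priors `lambda ~ Beta(1, 10)` (truncated to
[0, 0.5]), m uniform over the observed signal range padded 10%, w
log-uniform over [0.01, 2 x range]. Three bounded parameters make a grid
both deterministic and cheap; there is no MCMC to tune or to fail silently.
The fit reports marginal posterior means, equal-tailed 95% credibility
intervals whose endpoints are grid nodes bracketing the 2.5%/97.5%
cumulative marginal mass, the maximum-likelihood node, and the full grid
for joint (m, w) density plots; `summary()` prints the table. Parameter
recovery (coverage and bias of the threshold under simulated observers) is
checked in the acceptance suite.

Human-style confidence levels map to numerical values 1, 2/3, 1/3, 0
(high/moderate/low/none) and are averaged over labellers; images without
annotations are excluded from fitting with a logged count.

## The synthetic cytology benchmark

The generator renders schematic single cells on a 32x32 RGB canvas:
anti-aliased discs for cell and nucleus (multi-lobed, with Poisson-count
granules at `granule_density` per 100 px^2 of cell area), cytoplasm hue in
HSV, per-image jitter on the continuous parameters (relative SD `jitter`;
hue gets an absolute jitter of `jitter * 36` degrees since relative spread
on a circle is meaningless), and uniformly random cell pose. Imaging
domains apply zoom → blur → hue shift → contrast → compositing over a
uniform background, in that order, to a separately tracked foreground
layer, so the identity domain is exactly a no-op.

The five default classes emulate the gross morphology of common
leukocytes (neutrophil: three lobes, sparse granules; lymphocyte: large
round nucleus, blue cytoplasm; monocyte: large cell, two lobes;
eosinophil: orange dense granules; basophil: dark dense granules). A
held-out anomalous class (ring-shaped nucleus, green hue — a schematic
nucleated red-cell precursor) and an anucleate smudge "artefact" class
support the anomaly protocol. The morph continuum interpolates all
continuous fields between two classes at parameter (1+signal)/2 toward the
first (signal 0 = exact midpoint, maximally ambiguous; signal 1 = pure
first class; integer fields round half-up), and the simulated expert panel
labels images correctly with probability `1/K + (1-1/K)(2 sigmoid(slope ·
signal) - 1)`, reporting a confidence level by quantizing that probability
through bins (0.95, 0.8, 0.5).

The benchmark pool is 300 images per class, split 70-10-20
(train/validation/test, stratified, seeded); the validation split carries
all calibration (w_t, confidence rescaling, anomaly profiles) and is
frozen before the test split is touched — these orderings are enforced by
`ProtocolViolation` assertions, not conventions. Anomaly evaluation scores
a 100-image stratified test subset against 100 held-out-class images.
Domain-shift and low-data protocols follow the same hygiene: shifted test
sets are freshly generated (disjoint source ids, audited), zoom
augmentation (uniform 1.0–2.2) is available at training, and the low-data
protocol resamples fresh per-class subsets per repetition, trains with
periodic parameter snapshots and selects the snapshot with the highest
validation accuracy.

### What passing the benchmark shows — and what it does not

The generator targets *structural* fidelity (classes separable by the
same kinds of features a morphologist uses) and makes no attempt at
photometric realism: no camera noise model, no staining chemistry, no
focal-plane structure, no touching cells, and intra-class variability is
parametric jitter rather than biological heterogeneity. Passing the
benchmark demonstrates that the algorithms are implemented correctly and
that the system behaves as the theory predicts on images whose generative
process is known — not that any particular accuracy will transfer to
clinical smears. The deliberately schematic classes also make the task
easier than real cytology; the desk-scale numbers should be read as
properties of the method, not forecasts.

## Numerical choices and degenerate inputs

* Ties in the decision rule break to the lowest class index, with a
  logged warning.
* Zero-variance paired differences: p = 0 (positive mean) or p = 1.
* Constant calibration batches: confidence mapping is constant 0;
  constant score batches normalise to 0.5 (both warn).
* Macro metrics: a class never predicted contributes 0 precision to the
  macro mean (logged); balanced accuracy is macro sensitivity over classes
  present in the truth.
* Split apportionment uses largest remainders, so per-class counts are
  exact where divisible and off by at most one otherwise.
* Checkpoints store a SHA-256 parameter checksum; loads verify it.
* Reported JSON carries seeds and a config hash, never wall-clock fields,
  so identical runs produce identical bytes.

## Known limitations

* Training the denoiser in NumPy is CPU-bound; the defaults take a few
  minutes and scale linearly in steps. The backbone is intentionally
  small; the framework treats it as a replaceable contract.
* The profile normality score needs a labelled in-distribution calibration
  split with at least two images per class.
* The low-data protocol's checkpoint selection evaluates validation
  accuracy with the same eliminating classifier it will use at test; with
  very small validation sets this selection is noisy.
* Elimination p-values are nominal, not corrected for the repeated
  testing over iterations; the simulation check shows the realised
  per-test rate is in fact conservative, but the guarantee is empirical,
  not analytic.
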