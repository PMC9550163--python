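# Methods

## Problem and model

The package treats ultrasound quality rating as four-class supervised
classification (normal / noisy / blurry / distorted) over features that
describe *how an image responds to progressive smoothing* and *how its CNN
activations distribute*, rather than over raw pixels. The two feature
families are deliberately complementary: the multi-scale metric sweep is a
hand-designed, fully deterministic signature of degradation physics, while
the fuzzy CNN features summarise learned texture statistics.

## Multi-scale quantitative features

For T steps the image is filtered at kernels n = 2N−1, N = 2 … T+1, and 15
full-reference metrics are computed per step, always with the unfiltered
input as **reference** and the filtered image as **test**. This
orientation matters for the asymmetric metrics (SC, NAE, SNR, AD): the
filtered image plays the role of an estimate of the clean signal, and the
convention is fixed package-wide. Default T = 8 (kernels 3…17), the point
beyond which the step sweep stops adding discriminative signal in our
ablations; T is a config/CLI knob.

Metric conventions (all arithmetic double precision):

- intensities live in [0, 1], so PSNR/SNR use MAX = 1; a vanishing error
  term caps PSNR and SNR at ±100 dB instead of producing infinities —
  metric vectors must stay finite for classifiers;
- SSIM uses the standard published parameterisation: 11×11 Gaussian window
  with σ = 1.5, c₁ = 0.01², c₂ = 0.03², population (not sample) local
  covariance, mean taken over the valid-window map. For images smaller than
  11 px per side the window shrinks to the largest odd size that fits. The
  implementation is cross-checked in the tests against
  `skimage.metrics.structural_similarity` and against a windowed loop
  oracle;
- LMSE and EPI use the 3×3 Laplacian [[0,1,0],[1,−4,1],[0,1,0]] with
  reflect padding; EPI is the Pearson correlation of the mean-subtracted
  Laplacian responses;
- entropy uses 256 equal bins on [0, 1]; empty bins contribute zero;
- ratio metrics (SC, NCC, NAE, UQI, EPI, LMSE) return their
  identical-image value when numerator and denominator both vanish and are
  capped at ±10⁶ otherwise, again to keep vectors finite on degenerate
  inputs (constant images).

All filters use reflect padding — zero padding would inject an artificial
border error that grows with kernel size and contaminate the metrics.
Filter parameter defaults where a choice was open: Gaussian σ = kernel/6
(window spans ±3σ); bilateral σ_space = kernel/6, σ_intensity = 0.1.

## Fuzzy layer

The layer operates per channel over spatial positions only; this is the
only reading consistent with a 3×C output (1536 = 3×512). Parameters
follow the capped-ReLU ceiling r_max = 6: p = 3, q = 4.5, r = 6. The
Gaussian spread σ is open in principle; the default σ = r_max/4 = 1.5
places q ± 2σ across the activation range and is exposed in
`MembershipParams`.

Mean-of-maxima is implemented in its standard fuzzy-logic sense: the mean
of the *domain* (activation) values at positions of maximal membership
degree. The collapse variant that averages the maximal degrees themselves
(which reduces to "the max degree") is available behind the
`collapse_to_degree` flag for comparison but is not the default, since it
discards the activation scale entirely. Ties at the maximum are detected
with relative tolerance 1e−6: activation plateaus are common after capped
ReLUs and pooling, and exact floating-point equality would split ties
arbitrarily.

## Backbone

Two architectures, both plain numpy with ReLU6 activations throughout
(guaranteeing the fuzzy layer's [0, 6] domain):

- `vgg19_shape`: the canonical VGG-19 layout (2,2,4,4,4 conv layers,
  64/128/256/512/512 channels, 2×2 max-pool per block). It exists for the
  dimension contracts (224×224 → 7×7×512 → 1536 fuzzy features) and as a
  random-weight feature extractor; pretrained transfer weights are not
  shipped. Grayscale inputs are replicated to three channels.
- `smallnet`: three blocks (8/16/32 channels), the experiment-scale
  network; 64×64 → 8×8×32 → 96 fuzzy features. One forward pass costs
  milliseconds, so the whole pipeline runs on one CPU in seconds.

Convolutions are evaluated as a sum over the nine kernel offsets of a
shifted (H·W × C_in) × (C_in × C_out) matrix product — memory-light and
BLAS-fast. Fine-tuning updates only the blocks at/after `trainable_from`
(the last block by default, mirroring conv-block-5 fine-tuning at full
scale) plus a dense softmax head on the fuzzy features, with plain SGD,
weight decay and inverted dropout. Backpropagation through the
mean-of-maxima treats the selected positions as constants and splits the
gradient evenly among them — the same subgradient convention as
max-pooling. The frozen prefix is computed once per image and cached. The
seed fixes weight initialisation, the stratified train/validation split
(80/20) and batch order, so identical configs reproduce bit-identical
validation accuracies. A non-finite loss aborts with a
`TrainingDivergence` error naming the offending config.

## Particle swarm optimization

A maximizer over a bounded box: the textbook velocity/position updates
with fresh per-particle uniform draws each iteration, personal and global
bests updated under the same (maximization) convention, positions clamped
to the box and velocities to half the box width per dimension (absorbing
walls prevent divergence on plateaus). Defaults w = 0.7, c₁ = c₂ = 1.5,
20 particles, 30 iterations; the stopping rule is the fixed iteration
budget. Fitness for hyperparameter tuning is `train`'s validation
accuracy; particles encode training hyperparameters (log₁₀ learning rate,
batch size, weight decay, dropout), never raw layer weights — encoding
millions of weights as particle coordinates is computationally
implausible. Integer dimensions are decoded by rounding. Non-finite
fitness values (including training divergence) are recorded as −inf with
a warning.

## Evaluation protocol

A stratified 80/20 holdout is drawn first; every model comparison and
ablation runs as stratified 5-fold cross-validation *inside* the 80%
portion, and the untouched 20% receives a single final evaluation — the
only composition of the two protocols that avoids test leakage. Reports
pool out-of-fold predictions into one confusion matrix from which
accuracy, per-class and macro precision/recall/F1 are derived
(identities asserted to 1e−12 in tests); ROC curves are one-vs-rest on
pooled out-of-fold class probabilities. Classifier defaults: random
forest with 100 trees, Gini, √d features per split; logistic regression
(L2) and 5-NN receive z-scored features fit on training folds only (tree
ensembles are scale-invariant and get raw features); XGBoost depth 6 /
100 rounds.

Feature selection: mRMR greedily maximises mutual-information relevance
minus mean redundancy on 10-bin quantile-discretized features; RFE drops
the lowest-importance decile by random-forest importance per round.
Default k_keep = 200. Both are provided for redundancy analysis; no
ordering against the full feature set is asserted, as the direction is
dataset-dependent.

## Synthetic data generator

Each image draws its own clean base: a Gaussian random field low-pass
filtered at σ = min(H,W)/10, rescaled into [0.25, 0.7], with 1–3 rotated
elliptic lesion regions of shifted mean, multiplied by mean-one Rayleigh
speckle at mixing strength 0.3 (the `speckle_scale`; a raw Rayleigh scale
parameter cancels under mean normalisation, so the knob is the mixing
strength). Degradations: the noisy class applies full-strength
multiplicative speckle plus additive Gaussian noise with σ ∈ [0.05, 0.2];
blurry applies Gaussian blur with σ ∈ [1.5, 4]; distorted applies a
smooth random warp of amplitude ∈ [2, 6] px plus contrast crush (slope
0.4–0.6 about mid-gray) and quantisation to 5–8 intensity levels. Ranges
were chosen once so that classes are separable but overlap at range
boundaries. Degradations are applied to *distinct* bases per image so a
classifier cannot memorise content instead of quality.

What the generator does **not** emulate: depth-dependent attenuation and
time-gain compensation, sector-scan geometry and its fan-shaped field of
view, acoustic shadowing/enhancement, probe-pressure deformation, or
vendor post-processing. Passing tests therefore demonstrate that the
pipeline's mechanics and contracts are correct and that its features
separate *these* degradation signatures; they do not certify accuracy on
clinical images.

## Experiment scale

The packaged experiments use 50 images per class at 64×64 with the
`smallnet` backbone (5-fold CV inside a 160-image training portion,
40-image holdout), a size at which the full pipeline — including the PSO
search (4 particles × 3 iterations, 4 epochs per fitness evaluation) —
completes in well under a minute on a single CPU while still exercising
every component end to end. At this scale the synthetic classes are
cleanly separable (cross-validated accuracy at or near 1.0); the
interesting quantities are the directional comparisons (more steps ≥
fewer; median ≥ mean filtering) and the contract that fusion never costs
more than sampling noise against the best single feature family.

## Known limitations

- Random-weight `vgg19_shape` features are a dimensional stand-in, not a
  substitute for transfer-learned representations.
- The numpy training loop is single-image-gradient based and sized for
  small experiments; it is not a general-purpose trainer.
- Mean-of-maxima is non-differentiable at tie boundaries; the subgradient
  convention used is standard but means training signals through the fuzzy
  layer are sparse when activations plateau.
- mRMR cost grows as O(k_keep · d · n); for the full 1656-feature vector
  with large k_keep it is the slowest component of the pipeline.
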