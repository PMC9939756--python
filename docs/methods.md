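# Methods

This note records the modelling choices behind `sarftex`: what the pieces
compute, the defaults and why, where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## PGLCM features

**Pyramid.**  Level 0 is the input image; each subsequent level is the
Gaussian-smoothed, 2×-downsampled predecessor (ceil-halving dimensions,
delegated to `skimage.transform.pyramid_reduce`).  Default 3 levels: with
the default distance set {1, 2, 4} this spans effective pair offsets of
1–16 source pixels, which covers both fine and coarse texture at typical
microscopy/mammography resolutions while keeping the top level of a 64×64
test image at a usable 16×16.

**Quantization.**  Intensities are uniformly binned to 16 gray levels
before co-occurrence counting (`floor(v·16/(max+1))`).  16 levels keeps
each GLCM at 16×16 (256 cells), dense enough to estimate from small
pyramid levels and cheap to reduce; it is configurable for sources with
more usable dynamic range.

**Offset convention.**  With rows growing downward, 0° pairs a pixel with
its right neighbour (0, +d), 90° with the pixel above (−d, 0), 45° the
up-right and 135° the up-left diagonal.  GLCMs are symmetric (both pair
orders counted) and normalized by default; symmetric matrices make the
offset sign immaterial.  Diagonal offsets use exactly (±d, ±d) — the
"distance" is the Chebyshev offset, not Euclidean.

**Haralick statistics.**  Contrast, correlation, energy and homogeneity.
Energy is the angular second moment Σp² (not its square root — conventions
differ and the choice is stated here because it changes values, not
rankings).  Correlation of a degenerate GLCM (zero marginal variance, e.g.
a constant image) is defined as 1: a constant is perfectly
self-correlated, and the convention keeps feature vectors finite.

**Fusion.**  For every (distance, angle, statistic), the statistic is
computed on each pyramid level's GLCM and summarized by its mean and
(population) standard deviation across levels.  Levels are the only
remaining axis once distance and angle are fixed in the feature name, so
the "std" aggregate measures scale dependence of the texture: a
self-similar texture has low std, a scale-localized one high std.
Aggregating over angles instead (making features rotation-invariant) was
the main design alternative; it was rejected because direction-specific
features are exactly what separates oriented textures, and rotation
augmentation is available when invariance is wanted.

## The self-attention network

Architecture, per head h of k (default k = 1; the single head is fully
determined by the global-attention averaging rule, and more heads add
parameters without adding signal on tabular feature vectors of this
size):

    Omega(X) = (1/k) sum_h X ⊗ softmax(W_h X + b_h)        attention, |F|→|F|
    dense(|F| → hidden) → SELU → dropout(0.2)
    dense(hidden → hidden) → sigmoid
    dense(hidden → n_classes) → softmax

with hidden = |F| by default.  Training: categorical cross-entropy, Adam
(lr 1e-3, β = 0.9/0.999), 20 epochs, batch 16, all seeded; the softmax is
computed shift-invariantly and SELU uses the standard self-normalizing
constants λ = 1.0507, α = 1.67326.  Loss per epoch is recorded on the
model.  A non-finite loss aborts with the epoch number.

**Initialization.**  Attention weights and biases start at zero, so
initial attention is exactly uniform and the refined features start at
X/|F|; dense layers use seeded Glorot-uniform draws (all-zero dense
weights would never break symmetry).

**Input scaling.**  Features are min-max scaled to [0, 1] inside
`train_san` (statistics stored on the model, applied at inference).  This
is a load-bearing choice for interpretability: with non-negative inputs,
a positive self-weight W_jj consistently raises attention on feature j in
the samples where the feature is large, so the attention-matrix diagonal
accumulates the feature's importance.  Z-scoring (also available via
`SANConfig.input_scaling`) centers each feature so the self-weight sees
both signs and the diagonal receives no consistent pressure; in our
benchmarks the diagonal then stays uninformative even when the per-sample
attention (carried by the bias) concentrates correctly.  Classification
accuracy is nearly identical under either scaling; the ranking quality is
not.

**Global attention and fusion.**  R_G = (1/k) Σ softmax(diag W_h): a
probability distribution over features.  Fusion is residual and
elementwise, F′ = F + F ⊗ (|F|·R_G).  The |F| rescaling makes uniform
attention classifier-neutral (F′ = 2F, which threshold-based trees cannot
distinguish from F); without it, fusing with uniform attention would still
be neutral for trees but the magnitudes would carry a spurious 1/|F|.
The unrescaled variant (F′ = F + F ⊗ R_G) is available via
`SANConfig.rescale_attention=False`.

## Forest and importances

Bagging is explicit: each of n trees (default 200) is fitted on a
bootstrap sample of size N drawn with replacement, with the index multiset
recorded so every tree's out-of-bag (OOB) complement is known.  Trees are
sklearn `DecisionTreeClassifier`s — Gini impurity, √|F| candidate features
per split, depth capped at d (default 20), per-tree seeds drawn from the
forest seed.  Prediction is the majority vote; vote fractions are the
probability output; ties go to the lexicographically smallest class label
so results are deterministic.

**OOB permutation importance.**  For each tree k with non-empty OOB set
B_k and each feature j: permute column j within B_k (one seeded
permutation by default; `n_repeats` for more), and take the increase in
misclassification count over the unpermuted OOB predictions, divided by
|B_k|; average over trees.  A constant feature scores exactly 0 (the
permutation is a value-level identity).  Negative values — permutation
accidentally helping — are *not* clipped: they are informative about
noise features and clipping would bias averages.  Trees with empty OOB
sets are skipped with a warning (possible only for tiny N).

**Grid search.**  Exhaustive over (depth, n_trees) — default ranges 10–30
and 190–230, step 1 — scored by stratified k-fold CV mean accuracy
(default k = 5) on shared folds, so scores are comparable across
candidates and invariant to grid ordering.  Ties break to the smallest
depth, then the smallest tree count (the cheapest of the equally good
models).

## Pipeline conventions

The train/tune commands split the feature table stratified by class
(default 30% held out) before any fitting; grid search sees only the
training split.  Every run directory gets a `run_manifest.yaml` with the
configs, seeds and package version; identical manifests reproduce
identical outputs bit for bit.  Augmentation balances classes to a target
count by applying seeded, uniformly drawn lossless operators (quarter-turn
rotations, axis flips) and Pillow enhancements (brightness, color,
contrast, sharpness; default factor 1.2) to randomly chosen originals,
with provenance recorded; originals are always retained.  Only lossless
rotations are offered — arbitrary angles would interpolate and change the
co-occurrence statistics being measured.

## Synthetic benchmarks: scope and honesty

`gen_texture_dataset` produces oriented sinusoidal gratings (random
phase), Gaussian random fields (controlled correlation length) and
checkerboards (random offset), with additive Gaussian noise, clipped to
8-bit.  These were chosen because their GLCM behaviour is analytically
predictable — a grating varying along x has high 0° contrast and near-zero
90° contrast at offsets below its period — so feature extraction can be
validated against expectations, not just against itself.
`gen_tabular` produces class-shifted normal informative features (class c
mean = c·effect, sd 1; default effect size 3, i.e. well-separated but
noisy) among standard-normal noise features, with the informative index
set returned for recovery tests.

What passing these benchmarks shows: the mechanics are correct — features
separate what they should separate, attention and permutation importance
recover planted signal, the pipeline is deterministic and accurate on
separable texture.  What it does not show: performance on real
histopathology or mammography, which differ in stain/intensity
variability, spatial nonstationarity, label noise and class imbalance
far beyond what these generators emulate.  Published headline accuracies
on public datasets are not reproduced here because the images are not
bundled; the packaged confusion matrices reproduce the *metric
arithmetic* of those experiments, not the experiments themselves.

Problem sizes in the test and acceptance runs are deliberately modest —
64×64 images, ≤ 200 images per run, 500×20 tabular benchmarks, ten seeds
for stochastic properties — chosen as the smallest sizes at which the
properties under test are stable.

## Known limitations

- The SAN is a shallow feed-forward network trained in numpy; it is meant
  for feature weighting on hundreds of tabular features, not as a
  general deep-learning substitute, and has no GPU path.
- Attention-based and permutation-based importances of strongly
  correlated features are shared between them (both stay above noise, but
  each is diluted); neither method resolves which of two duplicates is
  "the" cause.
- GLCM features assume gray-level texture is the discriminative signal;
  color-dependent structure is discarded at luminance conversion
  (ITU-R 601 weights).
- Grid search at the default ranges fits 861 forest candidates × k folds
  and is the one genuinely expensive operation; narrow the ranges or the
  steps for interactive use.
- The model artifact is a Python pickle (it contains sklearn tree
  objects); it is portable across machines but not across major sklearn
  versions.  The SAN alone has a JSON artifact (`AttentionModel.save`).
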