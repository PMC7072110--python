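# Methods

This note documents the models, conventions and numerical choices behind
`boneal`, and what the synthetic experiments do and do not demonstrate.

## Synthetic phantoms

A phantom is the union of an elliptical palm (semi-axes 0.17·rows,
0.16·cols, centered at 70%/50% of the frame) and five vertical finger
capsules rooted just above the palm center. One latent `maturity`
m ∈ [0, 1] drives:

- **geometry**: finger length = palm semi-major axis × patternᵢ ×
  (0.8 + 1.1·m), with pattern (0.62, 0.88, 1.00, 0.92, 0.70) from thumb to
  pinky. The mean finger-length-to-palm ratio is therefore *exactly linear*
  in m (Pearson r = 1 with jitter off), which makes age recovery a
  well-posed estimation problem;
- **photometry**: hand intensity 140 + 50·m on a background of 30, a
  secondary age cue;
- **age**: `age_months = round(228 × m)`, covering the 0–228 month span of
  pediatric hand archives.

Nuisance variation emulates how clinical radiographs vary in intensity,
contrast and brightness: brightness offset U(−20, 20), contrast gain
U(0.85, 1.25), Gaussian noise with σ up to 8 intensity units, 0–3 bright
rectangular artifacts (labels/collimator edges) kept strictly outside the
hand's bounding box so ground-truth masks stay unambiguous, and ±4%
multiplicative jitter on the geometric dimensions. Sex is Bernoulli(1/2)
and, in the generator, independent of geometry; experiments that need a
sex-dependent maturation map construct it explicitly.

Everything derives from one `numpy` generator seed; rendering is a pure
function of the drawn parameters (noise and artifact placement use a
per-phantom `render_seed`), so datasets are byte-reproducible.

**What the phantoms do not model:** bone texture, carpal structure,
growth plates, anatomical pose variation, annotation noise (the synthetic
oracle is exact) and any realistic sex difference in maturation. Passing
tests demonstrate that the *algorithms* behave as specified — not that the
pipeline reaches clinical accuracy on radiographs.

## Segmentation network

A parametric U-Net: per encoder stage one 3×3 same-padded convolution +
ReLU then 2×2 max pooling; a bottleneck convolution doubling channels
once more; per decoder stage nearest-neighbor ×2 upsampling, concatenation
with the matching encoder activation, and a 3×3 convolution + ReLU; a 1×1
sigmoid head. Channel widths are `base_filters · 2^stage`. Defaults:
depth 4 / base 32 for realistic runs; the test and experiment
configuration is depth 2 / base 4 at 64×64 (a few thousand parameters),
chosen so that full active-learning experiments run in minutes on one CPU.

The committee's disagreement features are the global average pool of the
bottleneck activations (length `base_filters · 2^depth`): the deepest,
most compressed description of the image, and the natural single vector
summarizing what a member "sees".

Training minimizes the *per-image summed* pixel-wise binary cross entropy
(probabilities clipped to [1e-7, 1 − 1e-7] inside the loss value;
gradients use the exact `p − y` form), with mini-batches averaging the
per-image sums. The optimizer is Adam (lr 1e-3, β = 0.9/0.999, ε = 1e-8);
shuffling is seeded per epoch from the model seed, and initialization is
He-scaled from the config seed, so equal configs give bit-identical
models. The implementation is vectorized NumPy (im2col convolutions);
inference is a deterministic forward pass.

## Active learning

Committee members share one architecture and differ only in seed
(`master_seed + index`). Each query epoch: every member trains one epoch
on the current labeled pool; all unlabeled images are re-scored; the
`queries_per_epoch` images with the lowest aggregate pairwise cosine
similarity are annotated and join the pool for the *next* epoch. The
pairwise similarity is defined for two members; for k > 2 the default
aggregate is the mean over all k(k−1)/2 pairs (the least-committal
symmetric extension), with `min` available since "lowest similarity"
could also be read as the worst pair. Ties in the score break
lexicographically by image id, making query selection fully deterministic.
If the unlabeled pool runs dry, querying stops and training continues.

The final segmentation output is the member with the best Dice on a
held-out split — members are not ensembled at inference. The FSL baseline
trains a single net on a seeded random subset of the same annotation
budget for the same number of epochs.

The reference schedule (100 initial + 10/epoch × 20 epochs + 80 post
epochs = 300 annotations) is checked at full size on a 400-phantom pool;
the AL-vs-FSL comparison runs a proportionally scaled schedule (20 initial
+ 5/epoch × 8 epochs + 12 post epochs = 60 annotations on a 200-phantom
pool, k = 3, three master seeds) so that the whole paired experiment stays
within a few CPU-minutes. On these phantoms segmentation is easy enough
that both arms approach Dice ≈ 0.99 and AL's advantage is small; the
experiment establishes the direction (AL ≥ FSL at matched budget), not an
effect size transferable to radiographs.

## Preprocessing

- `standardize`: per-image (img − mean)/std with the *population* standard
  deviation; a constant image is an explicit error rather than a silent
  divide-by-zero.
- CLAHE: per-tile histograms (256 bins) clipped at `clip_limit` times the
  uniform bin height, excess redistributed evenly, equalized via the CDF
  convention `round((cdf − cdf_min)/(N − cdf_min) · 255)`, and mappings
  bilinearly interpolated between tile centers. With one tile and no
  clipping this is exactly global histogram equalization. A tile whose
  histogram occupies a single bin maps identically (flat stays flat).
  Defaults clip_limit 2.0, tiles 8×8. CLAHE is applied to raw intensities
  before standardization (`clahe_stage: before_norm`); a post-segmentation
  stage is available since either ordering is defensible.
- `binarize`: ŷ ≥ threshold → 1, default 0.5. `crop_to_mask`: tight
  bounding box plus margin, half-open intervals, clipped to the frame.

## Age regression

Ages scale as months/228 onto [0, 1] and predictions are projected back
(clipped to [0, 228] with a logged warning if outside). Estimators are
scikit-learn's SVR (linear kernel, C = 1.0, tol = 1e-3, ε = 0.01 in scaled
units) and KernelRidge (α = 1.0, linear kernel; a degree-3 polynomial
kernel is exposed as an alternative since "cubic" is sometimes quoted for
this configuration).

**Estimator convention.** Features are z-scored on the training data and
KRR is fit on centered targets — an unpenalized intercept, since
KernelRidge has none: ŷ = ȳ + K_z (K_z + αI)⁻¹ (y − ȳ) on standardized
features. Without this, the regularizer's strength depends on arbitrary
feature units, and on near-collinear low-variance features (exactly what a
small GAP vector or the phantom geometry produces) the fixed α = 1.0
over-shrinks the signal. The closed-form oracle used in tests includes the
same convention.

Cross-validation is seeded shuffled 5-fold; metrics are computed in
months on pooled out-of-fold predictions (each sample contributes once).
Ensembles are BaggingRegressor (bootstrap mean) and AdaBoostRegressor
(AdaBoost.R2, linear loss) over KRR bases, seeded. Per-sex stratification
fits and cross-validates 'all', 'male' and 'female' cohorts; an optional
per-age-bin downsampler (12-month bins) balances the age distribution.

The recovery experiment — 500 jitter-free phantoms, geometry features,
additive N(0, 6 months) age noise — lands at CV MAE ≈ 4.7 months against
the σ·√(2/π) ≈ 4.8-month noise floor: the estimator neither underfits
grossly nor hallucinates precision beyond the noise.

## Feature extraction

`FeatureBackbone` maps an image to a (rows × cols × channels) tensor;
global average pooling flattens it. The desk-scale default backbone is
the best committee member's encoder (it has already learned hand
structure); ImageNet-scale CNNs are out-of-scope plug-ins behind the same
interface and never required by tests. 2-D embeddings use IncrementalPCA
or KernelPCA (linear/RBF; RBF bandwidth = inverse median pairwise squared
distance). Embedding signs are fixed by making the largest-magnitude
entry of each score column positive; rank-deficient inputs take an
explicit degeneracy path (warning, zero second column).

## Pipeline and determinism

One YAML config with per-stage blocks plus a single global seed drives
`generate → al-train → segment → features → regress → evaluate`; every
derived seed (committee members, splits, folds, ensembles) comes from the
global one, so two runs produce byte-identical metric reports. Artifacts
are PNG (images/masks), CSV (manifest, history, features, embeddings,
reports), `.npz` checkpoints with embedded config, and a JSON-lines run
log. Images are resized bilinearly to the network input; masks
nearest-neighbor.

## Known limitations

- The NumPy nets are desk-scale by design; no augmentation, GPU path or
  large-architecture reproduction.
- The phantom task saturates quickly, so segmentation comparisons have
  small dynamic range near Dice 1.
- The encoder-derived feature vector is 16-dimensional in the default
  desk configuration; its age regression is far weaker than what
  archive-scale pretrained backbones achieve, which is why the regression
  acceptance experiment uses the geometry features instead.
- Lin's CCC is computed with population moments; Dice of two empty masks
  is an error, not 1.
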