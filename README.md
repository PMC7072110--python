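# boneal — annotation-efficient bone age assessment

Bone age assessment (BAA) estimates skeletal maturity, in months, from a
hand/wrist radiograph; the discrepancy between bone age and chronological
age flags growth and endocrine disorders. Automated BAA pipelines first
segment the hand from the raw radiograph (removing labels, collimator
edges and background), then regress age from deep image features. The
bottleneck is annotation: training a precise segmentation network normally
needs thousands of expert-drawn hand masks.

`boneal` implements a complete BAA pipeline whose segmentation stage needs
only a few hundred annotations, and makes every stage runnable and testable
at desk scale on procedurally generated hand phantoms — no clinical data,
GPU, or pretrained weights required.

## The method

**Query-by-committee (QBC) active learning for segmentation.** A committee
C = {θ₁, …, θ_k} of U-Nets shares one architecture but distinct
initialization seeds and trains on the same labeled pool L, leaving a pool
U unlabeled. After each training epoch every member extracts a deep
feature vector (global average pooling of its bottleneck activations) from
each unlabeled image, and the committee's agreement on image x is scored by
the mean pairwise cosine similarity

    sim(vᵢ, vⱼ) = vᵢ·vⱼ / (‖vᵢ‖‖vⱼ‖),

where vᵢ is member θᵢ's feature vector for x. The images with the *lowest*
similarity — the ones the committee disagrees about most — are sent to the
oracle for annotation and join L for the next epoch. The reference
schedule (100 initial labels + 10 queries/epoch for 20 epochs, then 80
epochs without querying) totals 300 annotations. A fully supervised
baseline (FSL) trained on a random subset of the same budget is the
comparison arm.

**Segmentation network.** An encoder–decoder U-Net with skip connections,
parametric in depth and base filter count, with a sigmoid head trained by
the per-image summed pixel-wise binary cross entropy
Σᵢ [−yᵢ log ŷᵢ − (1−yᵢ) log(1−ŷᵢ)] under Adam. The network and its
training loop are implemented in vectorized NumPy.

**Features and regression.** Segmented, cropped hand images pass through a
feature backbone (by default the best committee member's encoder; large
pretrained CNNs plug in behind the same interface), are flattened by
global average pooling, and optionally inspected via incremental/kernel
PCA 2-D embeddings. Ages are scaled from [0, 228] months to [0, 1] and
regressed by linear-kernel SVR (C = 1.0, tol = 1e-3) or kernel ridge
regression (α = 1.0), singly or as Bagging / AdaBoost.R2 ensembles, with
5-fold cross-validation and optional per-sex stratification. Results are
reported as MAE and RMSE in months plus Lin's concordance correlation
coefficient (CCC).

**Synthetic phantoms.** Each phantom is an elliptical palm plus five
finger capsules on a dark background; a latent maturity in [0, 1] drives
finger length relative to the palm (linearly) and maps to age via
`round(228 × maturity)`. Brightness, contrast, noise and off-hand bright
artifacts emulate the appearance variance of clinical archives. Ground
truth masks come free, so the synthetic oracle is exact.

## Worked example

Run the full pipeline on 60 phantoms (generate → active learning →
segmentation → features → regression → evaluation):

```bash
boneal pipeline --seed 11 --out work
```

`work/reports/segmentation.csv` then contains the held-out segmentation
quality of the best committee member — trained with only 20 annotations
(10 initial + 2 per epoch × 5 query epochs) out of 45 training images:

```
strategy,n_test,sensitivity,specificity,dice
AL best member,15,0.9196,0.9869,0.9145
```

i.e. 91% of hand pixels are recovered with 99% background specificity.
`work/reports/regression.csv` holds the cross-validated age regression on
the encoder features; at this miniature scale (60 images, a 16-dimensional
segmentation-trained feature vector) the CCC of about 0.69 shows the
features carry real age signal, while the MAE (about 42 months) reflects
how far a desk-scale feature extractor is from an archive-scale pretrained
backbone. The age signal itself is fully recoverable: regressing on the
phantoms' geometry features gives an MAE of ~4.7 months against a 6-month
noise floor (see below).

The query history (`work/al_history.csv`) records, per epoch, the mean
member loss, which images were queried and their disagreement scores.

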