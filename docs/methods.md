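# Methods

## Overview

`clemalign` automates the registration step of correlative light and electron
microscopy (CLEM) for single 2D planes.  Direct intensity-based alignment of
an EM image to a fluorescence image fails because the two modalities have
unrelated contrast.  The workflow sidesteps this by *in-silico labeling*: a
small convolutional network is trained on manually aligned (EM, chromatin)
pairs to predict the fluorescent chromatin channel from the EM image alone.
The predicted ("virtual") chromatin image lives in the EM pixel frame and has
fluorescence-like contrast, so the experimentally measured chromatin channel
can be registered to it with ordinary mono-modal machinery.  The recovered
2D similarity transform (rotation θ, isotropic scale s, translation t — 4
degrees of freedom, no reflection) is then applied to every other
fluorescence channel of interest.

The biological anchor is heterochromatin: dense chromatin patches are
electron-dense (dark) in EM and Hoechst-bright in fluorescence, so the same
puncta exist in both modalities with inverted polarity.  The method is well
posed only when at least three such puncta lie in the field of view; the
synthetic generator and all defaults respect that constraint.

## Coordinate and transform conventions

Pixel indices are 0-based; `x` is the column index (rightward), `y` the row
index (downward); coordinates refer to pixel centers.  A transform acts as
`p' = s·R(θ)·p + t` about the origin; helpers convert to/from
center-anchored parameterizations (rotations of a field of view are only
meaningful about its center).  Stored transforms map *moving* (measured
fluorescence) coordinates into the *fixed* (EM / predicted chromatin) frame;
warping the moving image resamples through the inverse map (bilinear or
nearest), with out-of-source pixels set to 0.  Transform parameters are
serialized to a minimal XML element
(`<similarity_transform theta_deg=… scale=… tx_px=… ty_px=… pixel_size_nm=…
moving=… fixed=…/>`) written with 17 significant digits, which round-trips
below 1e-9 relative error.  Pixel sizes come from TIFF resolution metadata
(baseline inch/cm units or ImageJ-style micron units); a missing pixel size
is a hard error unless the caller passes one explicitly, because nm-scale
error reporting is meaningless without it.

## Synthetic correlative scenes

The simulator is the package's stand-in for serial-section correlative data
(srAT-style SIM + SEM pairs).  One `SyntheticScene` holds the ground truth —
elliptical nuclei, non-overlapping puncta `(x, y, radius, intensity)`, and a
known EM→fluorescence similarity misalignment — and both modality images are
rendered from it deterministically (every random stream is derived from the
scene seed).

Defaults, chosen once to emulate the imaging regime the method targets:

| parameter | default | rationale |
|---|---|---|
| field of view | 320 × 320 px | 8 µm; large relative to the 3125 nm benchmark shift, so a shifted field still holds ≥ 3 puncta |
| pixel size | 25 nm/px | makes the 3125 nm protocol shift an exact 125 px |
| nuclei / puncta | 2 nuclei, 4–7 puncta each | ≥ 3 landmarks guaranteed per field |
| punctum radius | 75–150 nm | heterochromatin-patch scale |
| fluorescence PSF σ | 60 nm | SIM-like (~140 nm FWHM) |
| EM noise / texture | Gaussian σ 0.03 / filtered-noise texture σ 0.05 | detector noise + cytoplasmic granularity on a [0,1] scale |
| fluorescence noise | scaled Poisson (200 counts at unit intensity) + Gaussian σ 0.01 | shot + read noise |
| misalignment | θ ∈ ±10°, s ∈ [0.97, 1.03], shift ∈ ±500 nm | coarse pre-alignment typical of section re-localization |

EM rendering: mid-gray cytoplasm with smooth texture, a slightly darker
nucleoplasm (soft-edged ellipse), puncta as dark soft-edged disks, additive
Gaussian noise.  Fluorescence rendering: analytic sum of Gaussians at the
punctum positions (mapped through the true transform when the misaligned
channel is requested) over a constant background, with Poisson-plus-Gaussian
noise.  What the simulator deliberately does **not** model: organelle
ultrastructure, membranes, section folds or local (non-similarity)
distortion, uneven illumination, 3D structure.  Tests passing on this data
therefore demonstrate the pipeline's geometric and statistical correctness,
not robustness to every real-world artifact; on real data the in-silico
labeling step carries that burden and retraining per dataset is expected.

## Preprocessing

EM contrast varies strongly between acquisitions, so EM images pass through
a configurable chain before training and prediction: global (non-adaptive)
histogram equalization with 256 bins — each pixel mapped to its empirical
CDF value — followed by (1, 99.8) percentile normalization (values outside
[0, 1] are kept, not clipped).  Equalization is rank-based and therefore
invariant to affine intensity rescaling; normalization is affine and defines
the network's input scale.  The chain is embedded in the model artifact and
applied exactly once per image at both train and predict time — silent
train/test intensity skew is the main failure mode of this model family.
Chromatin targets are percentile-normalized per image to a common scale.
EM polarity is left untouched (puncta stay dark); the network learns the
polarity flip itself.

## In-silico labeling network

A plain 2D U-Net regressor: 3 resolution levels, two 3×3 conv + ReLU layers
per level, 16 base filters doubling per level, 2×2 max pooling, nearest
upsampling with a channel-halving conv, skip concatenation, and a linear
1×1 output head.  The engine is a compact pure-numpy implementation
(im2col convolution with hand-derived backpropagation, Adam); float32
throughout, fully deterministic given the seed, verified against numeric
gradients and a scipy correlation oracle in the test suite.

Training: L1 (MAE) loss by default — robust to the heavy-tailed shot noise
on the fluorescence targets — Adam at 1e-3, batch size 8, random 64 px
patches sampled at identical coordinates in both images, a pair-level
validation split (10%), and per-epoch train/validation loss recorded in the
model artifact.  The documented production schedule is 150 epochs at batch
size 8; the **reduced CPU preset** used by the tests and the acceptance
protocol is 10 epochs × 6 patches/pair on 30 pairs, which already drives the
training loss to its plateau on the synthetic task (the loss curve flattens
after ~8 epochs) and reaches held-out prediction correlations ≈ 0.95.

Prediction pads reflectively to a multiple of 8 (pool^depth) and, for large
inputs, evaluates tiles with a surrounding context margin of
`max(overlap, receptive field ≈ 52 px)` real-image pixels, keeping only each
tile core — so tiled and single-shot predictions agree to float precision.

## Registration

The measured chromatin (moving) is registered to the predicted chromatin
(fixed) in five stages:

1. **Blob detection** — multiscale Laplacian-of-Gaussian maxima
   (`skimage.feature.blob_log` candidates on the min-max-normalized image),
   sub-pixel localized by a quadratic fit to the scale-normalized LoG
   response; puncta are the implicit fiducials.
2. **Description & matching** — a rotation-invariant radial descriptor
   (per-ring mean and spread of intensity out to 12× the keypoint scale, so
   it encodes the surrounding blob constellation rather than the
   near-identical local spot profile), mutual-nearest-neighbor matching with
   a 0.8 ratio test.
3. **Robust fit** — closed-form least-squares similarity (centered
   cross-covariance SVD, Umeyama scaling) inside RANSAC with 2-pair minimal
   samples, 3 px inlier tolerance, consensus ties broken by inlier RMS.  A
   rank-aware sign correction handles the collinear 2-point sample; a
   genuinely reflective optimum raises `REFLECTION_REQUIRED` (flips are
   outside the similarity model by design).
4. **Fallback / oracle** — if detection or consensus fails, an exhaustive
   grid search over rotation (3° steps) and scale {0.95, 1, 1.05}, taking
   each candidate's translation from the FFT cross-correlation peak
   (sub-pixel by quadratic fit) and scoring by zero-normalized
   cross-correlation (NCC) over the valid overlap.  Inputs larger than
   ~200 px are block-averaged 2× for the grid and the translation rescaled.
   With few, visually identical puncta the ratio test legitimately prunes
   most matches, so this route is common — and it doubles as the independent
   oracle the feature route is tested against.
5. **Refinement** — bounded Powell maximization of NCC over (θ, log s, tx,
   ty) about the image center, then a landmark polish: moving blobs are
   mapped through the estimate, mutually matched to fixed blobs within the
   inlier tolerance, and the closed-form fit re-solved on those pairs
   (two iterations).  The polish is preferred over the raw NCC argmax
   because intensity scores are slightly biased toward sub-pixel offsets —
   warping smooths the moving image's noise, which *raises* NCC against a
   clean prediction — whereas blob centroids localize to a small fraction
   of a pixel and are unbiased.

The result carries the transform, the geometric inlier count, NCC before and
after, and a status: `OK` requires ≥ 3 inliers and a non-degraded NCC;
failures return `LOW_FEATURES` / `NO_CONSENSUS` / `DEGRADED` instead of
raising.

## Evaluation protocol

Accuracy is measured by the known-perturbation protocol: a ground-truth-
aligned pair is perturbed by a known transform — aligned, a 3125 nm shift in
X, or a 90°/180° rotation about the image center (grid-exact perturbations
use lossless nearest-neighbor warping) — the workflow registers the
perturbed chromatin to the predicted chromatin, and the recovered transform
composed with the perturbation is compared with the identity.  The error is
the mean absolute per-axis displacement of that composition evaluated at the
scene's puncta, in nm (puncta are the biologically meaningful landmarks; the
estimator is a declared choice of this package).  A registration succeeds
when both axes stay below a threshold, 250 nm by default — gross failures
sit several hundred nm or more away, so the threshold cleanly separates the
two regimes; it is configurable.  A benchmark run (N scenes × the four
perturbations) reports per-record errors, the success rate, and a wide
per-image table.

## Problem sizes and numerical choices

The shipped protocol sizes are desk-scale by design: 30 training pairs
(within the 30–40 pair sizing guidance), 320² scenes, the 10-epoch preset,
10 held-out benchmark scenes.  RANSAC uses 2000 seeded iterations; Powell
refinement is capped at 400 function evaluations with 1e-4 parameter
tolerance; NCC requires ≥ 16 valid overlap pixels and ≥ 2 distinct values;
constant images short-circuit to `LOW_FEATURES`.  All randomness flows from
explicit integer seeds (scene seeds are spawned from a master seed via
`SeedSequence`); training is bit-reproducible on a given platform, and
loss-history agreement (not bit equality) is the cross-platform contract.

## Known limitations

* Similarity-only: no reflection handling, no affine or deformable
  component, no multi-section stack alignment.
* The descriptor stage is deliberately simple; on scenes with few puncta it
  often defers to the exhaustive fallback, which is slower but robust.
* The trained network transfers only to data resembling its training
  distribution; per-experiment retraining (optionally seeding the training
  set with a few manually aligned pairs from the same experiment) is the
  expected workflow on real data.
* Physical realism of the simulator is limited to what the registration
  problem needs (see above); it is not an EM texture model.
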