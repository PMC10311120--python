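# clemalign

Automated registration for correlative light and electron microscopy (CLEM)
via virtual chromatin staining.

In CLEM, fluorescence images must be overlaid on EM images of the same
sample region with high precision, but the two modalities have unrelated
contrast, so direct correlation-based alignment fails and registration is
traditionally done by hand or with fiducial markers.  `clemalign` automates
it for single 2D planes:

1. a small U-Net, trained on manually aligned (EM, chromatin) pairs,
   predicts the fluorescent chromatin channel from the EM image alone
   ("in-silico labeling") — heterochromatin puncta are electron-dense in EM
   and Hoechst-bright in fluorescence, so the mapping is learnable;
2. the experimentally measured chromatin channel is registered to that
   prediction with a 2D similarity transform
   `p' = s·R(θ)·p + t` (rotation, isotropic scale, translation — no
   reflection), estimated by LoG blob detection + RANSAC over a closed-form
   least-squares fit, with an exhaustive rotation/scale grid search as
   fallback and a landmark refit as the final polish;
3. the same transform is applied to every other fluorescence channel of
   interest, yielding the CLEM overlay and an XML record of the transform
   parameters.

The package also ships a synthetic correlative-scene simulator (nuclei,
puncta, modality-specific contrast and noise, a known ground-truth
misalignment) and the known-perturbation benchmark protocol — per-axis
absolute registration error in nm under an applied shift or rotation — so
the complete pipeline can be trained, evaluated, and tested with no external
data.  It is aimed at microscopy facilities and image-analysis developers
who need scriptable, reproducible CLEM registration.

The method is well posed only when at least three heterochromatin puncta
are in the field of view; sizing guidance for training is 30–40 aligned
ground-truth pairs.

## Worked example

Registering the measured (misaligned) chromatin channel to a chromatin
prediction on a synthetic scene, isolating the registration stage with the
simulator's ground truth as predictor:

```bash
python examples/register_measured_chromatin.py
```

```text
status: OK via exhaustive, 12 inlier landmarks
NCC before/after: -0.005 -> +0.948
estimated: theta=+5.208 deg, scale=1.0055, t=(+32.19, -32.04) px
truth:     theta=+5.209 deg, scale=1.0059, t=(+32.16, -32.11) px
residual at puncta: (0.7, 0.3) nm per axis
```

The images start essentially uncorrelated (NCC ≈ 0); after registration the
estimated transform matches the ground-truth misalignment to a few
thousandths of a degree and a few hundredths of a pixel, and the residual
at the puncta — the benchmark's error metric — is below 1 nm at 25 nm/px.  Other examples in
`examples/` cover scene simulation, U-Net training
(`train_virtual_staining.py`, several minutes), and the perturbation
benchmark.

A thin CLI wraps the same library calls:

```bash
clemalign simulate --out-dir scene --seed 3
clemalign train --n-pairs 30 --out-model model
clemalign run --em scene/em.tif --chromatin scene/chromatin_misaligned.tif \
              --model model --out-dir result
```

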