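# Methods

## Model and objective

The segmentation model is a 3D encoder–decoder convolutional network that
maps a 64³-voxel intensity window to a single-channel axon-probability map
over the window's 36³-voxel centre. The 14-voxel margin per side is the
defining geometric contract: predictions are made only where the network
has full spatial context, so whole-volume inference consumes an input
padded by the margin (a 188³ source cube for a 160³ labeled cube) and no
implicit padding ever occurs.

Training minimises a masked, class-weighted binary cross-entropy. Each
voxel's target is the axon indicator (label code 2); codes 1 (background),
3 (artifact) and 4 (edge) are negatives. The per-voxel weight is taken
from the class of the annotation — axon 1.5, background 0.2, artifact 0.8,
edge 0.05 — and voxels on unlabeled slices (code 0) carry weight zero, so
sparse annotation is handled by exclusion rather than imputation. The loss
is the weighted sum divided by the number of nonzero-weight voxels; a
window with no annotated voxels contributes zero (and warns). Probabilities
are clipped to `[1e-7, 1 − 1e-7]` before the logarithm.

The edge class exists to absorb annotator boundary uncertainty: the tiny
weight 0.05 means calling an edge voxel "axon" costs almost nothing during
training, and the evaluation metrics (below) forgive it entirely.

## Sparse annotation scheme

Labeled cubes carry annotation on every 20th z-slice starting at index 15
(0-based; the scheme's "15th slice" is interpreted as index 15 — the
one-slice ambiguity affects no algorithm, only which slices a phantom
marks). For a 160-slice cube that yields the 8 slices {15, 35, …, 155}.
`labeled_mask` recovers the annotated slices as exactly those containing
any nonzero code.

## Edge generation

Edges are derived per annotated 2D slice: every background voxel whose
in-plane 8-neighbourhood touches an axon voxel becomes code 4. The
computation is deliberately 2D — annotation exists only on isolated
slices, so a 3D boundary across unlabeled gaps is undefined — and edges
overwrite only background, never artifact, preserving the four-class
weighting. Re-deriving edges from the axon set of an edge-annotated volume
reproduces the same edge set (idempotence in effect), which the tests
assert against a brute-force dilation oracle.

## Window sampling and foreground oversampling

Training windows are anchored by their top-left-back corner, constrained
to `[0, dim − 64]` per axis so a full window always fits. Per cube and
epoch, 100 windows are drawn (7 training cubes → 700 volumes/epoch; at
batch size 6 that is 116 steps). With probability 0.3 the corner is drawn
uniformly from the list of axon-labeled voxels instead of uniformly over
the valid region, biasing training toward foreground-rich windows. Axon
voxels lying outside the valid corner region are clamped per-axis to the
nearest valid corner; an empty axon list falls back to the uniform draw.
When the label cube is smaller than the image cube (the 188 vs 160
layout), target voxels outside the labeled core read as unlabeled and
drop out of the loss via the zero weight.

## Augmentation

All geometric transforms apply one identical mapping to the input window
and its concentric label window. The label window is embedded in a
full-resolution canvas (background-filled), transformed with the image,
and re-cropped — this avoids boundary artifacts in the small target.
Images are resampled trilinearly, labels by nearest neighbour (no invented
codes). Axis flips are exact mirror copies. Rotations draw per-axis angles
uniformly within ±15°; elastic deformation smooths white noise with a
Gaussian of extent 9–13 voxels and scales it by a magnitude drawn from
0–200. These magnitudes follow the conventions of the common
batch-augmentation codebases and are configurable; each transform, when
enabled, is applied with probability 0.5 per sample (independent draws) —
the application schedule is a package choice, documented here because no
established convention exists. Out-of-domain voxels are filled with the
window median (a robust background estimate) and label code 1.

Intensity augmentation divides by the 16-bit maximum (65535) and applies
`x·s + c` with `s ∈ [0.8, 1.2]`, `c ∈ [−0.05, 0.05]`. Z-score
normalisation is deliberately absent: standardising each window removes
the absolute brightness cue that separates dim background from bright
axons, and measurably hurts that separation.

## Network, fine-tuning, and training loop

The network is built from explicit numpy layers (3³ same-padded
convolutions, batch norm, ReLU, 2× average pooling, nearest-neighbour
upsampling, skip concatenation, a centre crop to the output size, and a
1³ sigmoid head), with hand-written backward passes verified against
finite differences in the test-suite (float64 throughout; relative
agreement better than 1e-4 at ε = 1e-6). The default is 3 resolution
levels and 8 base filters; every spatial/width parameter is configurable
as long as the input size is divisible by 2^(depth−1). Training output
size is the same 36³ as inference (one printed description of the training
geometry says 32³; the package resolves the discrepancy in favour of the
margin-14 arithmetic that the 188→160 inference geometry requires, keeping
the margin configurable).

Fine-tuning can restrict learning to the first two, middle two, or last
two convolutional layers of the deterministic execution-ordered layer
list, or all of them. "Middle two" is defined as the pair straddling the
list midpoint (indices `(n−1)//2` and `(n−1)//2 + 1` of n layers) — a
documented convention, since no standard definition exists. Batch-norm
parameters remain trainable under every selector, and running statistics
keep updating by default (`update_bn_stats=False` freezes them). Frozen
parameters are bit-identical after any number of optimisation steps; the
tests assert this exactly.

Optimisation uses Adam (β₁ = 0.9, β₂ = 0.999). The learning rate is fixed
(1e-3 default; 1e-4 is the gentler fine-tuning alternative) or scheduled by
reduce-on-plateau: after `patience` epochs (default 10) without a new best
validation loss, the rate is multiplied by 0.1, floored at 1e-6. The
checkpoint kept is the epoch with the *lowest* weighted validation loss;
reloading it reproduces the recorded loss to 1e-6. A non-finite loss
aborts with a diagnostic rather than silently continuing.

## Inference fusion

Whole-volume prediction slides the input window across the padded volume;
each output window is accumulated with a weight map and every voxel is
finally divided by the sum of weights used there, i.e. a weighted mean.
In Gaussian mode the weight is `exp(−‖v − centre‖²/(2σ²))` with
σ = output_size/8 (the referenced sliding-window convention) and default
stride of half the output size; in plain mode weights are 1 and windows
abut (stride = output size). Remainder windows at the far edges shift
inward to end flush, guaranteeing full coverage for any stride ≤ output
size. Useful consequences, all asserted as invariants: a constant
predictor is reproduced exactly; fused values are convex combinations of
the covering windows' predictions; Gaussian and uniform fusion agree
wherever only one window covers a voxel. Mirrored (test-time-flip)
prediction is intentionally not implemented. Binarization is strict:
probability must exceed 0.5.

## Evaluation metrics

Counts are accumulated only over voxels with a nonzero label code.
Positives are axon voxels; background, artifact and edge voxels are
negatives (edge voxels receive no special treatment in TN/FN — the only
correction is EA). EA counts edge voxels predicted positive and is
subtracted from the false positives in the two edge-corrected metrics:

    accuracy        = (TP + TN) / (TP + TN + FP + FN)
    precision       = TP / (TP + FP)
    edge precision  = TP / (TP + FP − EA)
    recall          = TP / (TP + FN)
    F1              = 2·P·R / (P + R)
    edge F1         = 2·EP·R / (EP + R)

A zero denominator yields NaN (serialised as `null`), never a silent 0.
Metrics are computed per cube, not micro-averaged across cubes. Artifact
voxels predicted positive are plain false positives; no EA-like
forgiveness is extended to them.

## Phantom generator

The generator emulates the geometry and first-order photometry of labeled
light-sheet cubes: a dim background (mean 1200 on the 16-bit scale),
bright tubular axons (mean 12000) built as bounded-turning-angle random
walks dilated by a spherical element of radius 1–3 voxels, optional
brighter artifact spheroids (mean 18000), and additive Gaussian noise
(σ = 600) clipped to [0, 65535]. Labels are dense over the central cube
and sparsified to the every-20th-slice scheme. It does **not** model the
optical point-spread function, tiling/stitching seams, intensity
inhomogeneity, autofluorescence, or the morphological differences between
neurotransmitter systems — so green tests demonstrate that the pipeline's
mechanics (geometry, masking, weighting, fusion, bookkeeping) are correct,
not that the default network resolves real axons in real tissue.

## Problem sizes in the test-suite

The tests exercise the production geometry where it is cheap (window
arithmetic, 188³→160³ shape checks with a constant predictor) and shrink
everything else so the suite runs on one CPU: gradient checks on 8³
windows with 2 base filters, the end-to-end smoke run on a 32³ phantom
cube (48³ padded) with input 32, margin 8, 4 base filters, 8 samples and
10 epochs. At that scale the smoke run finishes in well under a minute
per epoch and still separates a trained model from an all-positive
baseline by a factor of ~5 in edge F1.

## Known limitations

- The numpy trainer is single-threaded BLAS-bound; it is meant for
  desk-scale experiments and correctness work, not for 100-epoch runs on
  real 160³ cube collections.
- Elastic-deformation magnitudes are expressed in the units of the
  underlying displacement-field implementation; transferring settings
  from other frameworks requires care.
- The phantom's tubes are homogeneous in intensity; there is no axon-like
  varicosity or branching.
- Checkpoints store raw arrays keyed by layer name; loading requires an
  architecturally identical network config.
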