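# Methods

## Problem setting

Focused ion beam–scanning electron microscopy (FIB-SEM) produces
near-isotropic 3D image stacks of hundreds to thousands of grayscale
slices. Manually annotating structures such as nuclei and nucleoli is the
bottleneck: in practice only a handful of slices (~0.3–3.3% of a stack) are
labeled. `cpseg` trains binary segmenters for one structure at a time from
those sparse labels, optionally exploiting the unlabeled slices through
cross pseudo supervision (CPS), and evaluates whole-volume predictions with
two Dice aggregates.

## Preprocessing

Slice brightness in EM stacks drifts along the milling axis, so each slice
is histogram-equalized independently: a monotone remap through the slice's
own 256-bin CDF. Constant slices are returned unchanged (equalization is
undefined on zero variance). The bin count is configurable (`n_bins`);
256 matches 8-bit acquisition depth.

Networks never see whole slices. A square *context window* (default
2048 px) is cut out and downsampled to a smaller *tile* (default 512 px),
trading resolution for spatial context. Images are downsampled by area
averaging; masks by nearest neighbour re-binarized at 0.5 so labels cannot
bleed across structure boundaries. Borders are reflect-padded — zero
padding would introduce artificial dark edges into EM intensities. At
inference, windows are placed at a configurable stride (default
context/2 so every interior pixel is covered twice), per-tile confidence
maps are bilinearly upsampled back and averaged where windows overlap, and
the stitched map is thresholded at 0.5. The downsampling method and
inference overlap are implementation choices; only the 2048→512 geometry is
part of the protocol.

## Sparse annotation and sampling

With `n` labeled slices out of `N`, slice `k` of the labeled set is
`floor((k + 0.5) · N / n)` — evenly spaced with symmetric margins. All
remaining slices form the evaluation (and, for CPS, the unlabeled training)
pool; labeled slices are never evaluated.

Nucleoli occupy a fraction of a percent of slice area, so uniform random
crops are almost always empty and a model trained on them collapses to
predicting background. The quota sampler makes the foreground guarantee
hard: `ceil(fg_quota · B)` crops of every batch (default quota 0.995) are
obtained by centering the context window on a uniformly drawn foreground
voxel with jitter up to a quarter window, re-drawn until the downsampled
mask tile is non-empty; the rest of the batch is uniform. If no annotated
slice contains foreground the sampler raises instead of silently degrading.

Unlabeled CPS batches have no masks to verify against, so candidate
foreground locations are *projected* from the labels: for an unlabeled
slice lying between two labeled slices, a pixel foreground on both flanking
slices belongs to a structure spanning the interval and — for the convex
blobs nuclei and nucleoli approximate — is foreground in between; outside
the labeled span the nearest labeled slice's foreground is used. Crops
centered this way (at least `cps_fg_fraction` of the batch, default 0.5)
are drawn preferentially from slices where the flanking-intersection
guarantee holds. This mechanism is an implementation choice; the protocol
only fixes the at-least-half-foreground composition of CPS batches.

Augmentation is the 8-element square-symmetry group (identity, three 90°
rotations, four reflections), chosen uniformly and applied to image and
mask alike. Restricting rotations to 90° multiples keeps masks binary and
avoids interpolation.

## Losses and schedules

Both objectives are soft Dice losses,

    DL(y, p̂) = 1 − (2·Σ y·p̂ + ε) / (Σ y + Σ p̂ + ε),

summed over the pixels of one sample and averaged over the batch — the
standard reading for heavily imbalanced masks, where a pooled-batch
denominator would let large-foreground crops dominate. ε = 1e−6 defines
the empty/empty case as loss 0.

CPS trains two networks of identical architecture with different weight
initializations. Each network's confidence map is scored against the
*other* network's hard pseudo-labels (threshold 0.5, ties to foreground):

    L_cps = DL(y₂, p₁) + DL(y₁, p₂)

Pseudo-labels are detached: no gradient flows into the network that
produced them. The total objective is `L = L_s + λ·L_cps` with λ following
a piecewise warm-up — 0.00001 while the networks cannot yet produce useful
pseudo-labels (epochs ≤ 5), a linear ramp `0.067·epoch − 0.335` over epochs
6–19, then 1. The small discontinuity between epoch 19 (0.938) and epoch 20
(1.0) is preserved as specified rather than smoothed. Epochs are 1-indexed;
the first training epoch is epoch 1.

With CutMix enabled, the unlabeled batch is mixed with a shuffled copy of
itself: per crop, a box with area fraction drawn from Beta(1,1) and sides
proportional to the square root of that fraction is pasted from the partner
crop, clamped into bounds with the fraction recomputed. Pseudo-labels are
computed on the *unmixed* crops (in evaluation mode, i.e. with running
normalization statistics) and mixed with the *same* boxes as the inputs, so
the consistency target never contains mixing-boundary label noise.

## Architectures

Two encoder–decoder families are provided behind one `Segmenter` contract
(B×1×S×S in, confidence in [0,1] out, terminal sigmoid):

- **resunet** — residual blocks (conv3–BN–ReLU–conv3–BN plus projected
  shortcut) at every level, 2×2 average pooling down, nearest-neighbour
  upsampling and skip concatenation up.
- **unetpp** — the nested-skip variant: node X(i,j) receives all previous
  nodes at its level plus the upsampled node one level deeper, with one
  segmentation head per nesting level. With deep supervision the output is
  the arithmetic mean of all heads' confidence maps.

Depth and base channel count are configurable; desk-scale testing uses
depth 2–3 with 4–16 base channels (10⁴–10⁵ parameters). The networks run on
a small in-repo reverse-mode autodiff engine over numpy (`cpseg.nn`:
broadcast arithmetic, 3×3/1×1 convolution via im2col einsum, batch norm,
pooling/upsampling, Adam), whose gradients are verified against central
finite differences in the test suite.

## Training

Adam with learning rate 3e−3 and no schedule; crop samplers are infinite,
so an epoch is a fixed number of steps (`steps_per_epoch`). Every CPS step
computes, for both networks, the supervised Dice loss on a labeled quota
batch plus the cross-supervision term on *both* batches — on the labeled
crops (where ground truth anchors the agreement, the "supervised CPS"
term) and on the unlabeled half-foreground batch — then updates both
networks and logs λ, both losses and a cheap validation Dice. Labeled-batch, unlabeled-batch and
CutMix randomness run on independent seeded streams so that setting
`lambda_max = 0` makes CPS training reproduce supervised training
batch-for-batch (verified parameter-exactly in the tests). If validation
predictions are all-background for three consecutive epochs the trainer
warns about background collapse. Model 1 of the pair produces reported
predictions; both are checkpointed.

## Evaluation

Per-slice Dice uses the convention that two empty slices agree perfectly
(Dice 1): a slice without the structure, predicted empty, is a correct
result. A corollary is that on empty-ground-truth slices the per-slice
value is a degenerate {0, 1} indicator — a single false-positive voxel
flips it from 1 to 0 — so analyses of per-slice *stability* across a
volume are performed over slices that contain the structure. Two volume aggregates are reported: the arithmetic mean of
per-slice Dice values, and the 3D Dice over all voxels of the evaluated
slices pooled. The average over-weights slices with little foreground (one
missed 10-voxel slice next to a perfect 100-voxel slice averages 0.5 while
the pooled value is 200/210 ≈ 0.95); the 3D value reflects the captured
fraction of the structure and is the recommended metric.

## Synthetic volumes

The generator emulates the *regime* of the real data, not its appearance:
large dark ellipsoidal nuclei with a bright rim, 1–3 dense dark nucleoli
strictly inside each nucleus occupying ~0.1% of volume by default (so
uniform crops are mostly empty and the quota sampler is actually
exercised), smooth background texture, Gaussian noise, and a smooth
per-slice brightness walk along Z scaled to a configurable amplitude (so
equalization has something to remove). Structures are prolate along Z: real
organelles at 4–6 nm isotropic resolution persist across far more slices
than the annotation spacing, and a desk-scale volume of 64 slices compresses
Z, so elongated ellipsoids preserve that persistence. Nucleolus radii are
rescaled so the integer per-nucleus count still meets the foreground
target. Masks mark the generated geometry exactly, and generation is
deterministic given the seed.

What the generator does *not* model: membrane/organelle classes beyond the
two structures, anisotropic texture, registration artifacts, and — most
importantly — the along-stack heterogeneity of real tumor volumes, where
distant slices can look qualitatively different from the labeled ones.
Passing tests on synthetic volumes therefore demonstrate the mechanisms
(quota guarantee, warm-up, stop-gradient, CutMix consistency, metric
behavior), not clinical segmentation quality.

## Problem sizes used in tests

Module and acceptance tests run on 64×128×128 and 64×512×512 volumes with
64→32 or 128→64 px tiling, depth-2 networks with 4–6 base channels, batches
of 4–16 crops, and 40-epoch training runs of 8 steps per epoch. These sizes
were chosen so the full suite exercises every mechanism on a single CPU in
minutes while preserving the sparse-foreground regime; the configuration
files accept the full-scale values (2048→512 tiles, deeper networks) for
real volumes.

## Known limitations

- The autodiff engine is deliberately minimal: stride-1 odd-kernel
  convolutions, 2× pooling/upsampling, no GPU; large-scale training is out
  of scope.
- The flanking-slice projection underlying unlabeled batch composition
  assumes convex, slowly varying structures; thin or branching structures
  would weaken the foreground guarantee.
- On homogeneous synthetic volumes the supervised baseline does not
  overfit the way it does on heterogeneous patient volumes, so the
  advantage of semi-supervision is correspondingly smaller there.
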