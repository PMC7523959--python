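# Methods

## Problem and model

The target data are paired fluorescence rasters of the same field: a DNA
stain that shows round, well-separated nuclei, and a cytoplasm stain that
shows irregular cell bodies.  Adherent macrophage-like cells cluster, and
the cytoplasm signal changes only faintly where two cells touch, so
cytoplasm-only segmentation tends to fuse neighbours.  The package's core
is a two-stage, single-foreground-class instance detector in the
Mask R-CNN family, extended with *feature pyramid fusion* (FPF): a
complete detector is first trained for nuclei; its feature pyramid is
then merged level-by-level into the pyramid of the cell detector, and
the nucleus-branch parameters are excluded from all gradient updates
while the cell branch trains.  At inference the embedded stage-1 model
still predicts nuclei, so one pass yields both instance sets.

Components, in the order the method runs:

1. **Backbone** — reduced ResNet-50: filter counts and bottleneck block
   counts halved relative to the standard network (stages
   (32,32,128)×2, (64,64,256)×2, (128,128,512)×3, (256,256,1024)×2 after
   a 7×7/64 stem), 1-channel input, batch normalization after every
   convolution, no convolution biases.  Downsampling sits on the 3×3
   convolution of the first block per stage (the post-2016 convention);
   the exact tally of trainable scalars is 3,780,288 versus 23,508,032
   for the standard backbone, a 6.2× reduction.
2. **Feature pyramid** — 1×1 lateral projections of C2…C5 to a common
   width, top-down nearest-neighbour upsampling with addition, 3×3
   smoothing, and a stride-2 subsampling of P5 for P6.  Pyramid width is
   256 by default and 128 in the desk-scale configuration.
3. **Fusion** — per-level merge of the frozen nucleus pyramid into the
   cell pyramid, by addition (widths unchanged) or concatenation
   (doubled).  After concatenation a 1×1 projection restores the pyramid
   width so head shapes are merge-invariant; the projection can be
   disabled.  Fusion acts on the final per-level pyramid outputs (after
   smoothing); fusing before smoothing would be a one-line change but is
   not exposed.
4. **Heads** — an RPN (3×3 conv + 1×1 objectness/regression, anchors of
   one scale per level: 32…512 px at aspect ratios 0.5/1/2), RoI Align
   (bilinear, one sample per output bin at the bin center, no coordinate
   quantization; 7×7 crops for the box head, 14×14 for the mask head),
   a two-layer fully connected box/class head, and a convolutional mask
   head producing 28×28 logits.
5. **Loss** — `L = L_rpn-cls + 2·L_rpn-box + L_cls + 2·L_box + 2·L_mask`:
   both regression losses (smooth L1) and the mask loss (per-pixel
   sigmoid binary cross-entropy on the 28×28 crop) carry weight 2.
   With border weighting enabled the per-pixel mask loss is multiplied
   by the weight-map crop for the proposal.

## Border weighting

Contours are instance-mask pixels 4-adjacent to a different label
(including background, and including the image frame).  The contour
indicator is convolved with the sampled Gaussian
`G(x,y) = 1/(2πσ²)·exp(−(x²+y²)/(2σ²))` (25×25 kernel, σ = 5 px,
zero padding), **peak-normalized over the image**, and mapped affinely to
`1 + (max_weight − 1)·v` with `max_weight = 2`.  Peak normalization makes
the maximum weight exactly 2 on contour pixels of every image that has
any contour; near the image border the zero padding can leave weights
slightly below 2, which is accepted.  Per-proposal crops are bilinear
resizes of the boxed region to the 28×28 mask grid, using the same
sample-point convention as RoI Align so weights align with mask logits.

## Ground-truth bootstrapping

Initial labels for new data come from classical segmentation: global
threshold (Otsu by default; fixed for noiseless data), morphological
closing (disk radius 2), connected components (4-connectivity), and an
area filter (30 px).  Cells overlapping more than one nucleus are split
by a generalized Voronoi rule: each cell pixel joins the nucleus with
the smallest Euclidean distance *to the nucleus mask* (distance
transform), not to its centroid — more robust for elongated nuclei.
Ties go to the lower nucleus label for determinism.  Interactive manual
refinement of the bootstrapped masks is out of scope.

## Post-processing

Three deterministic rules refine predicted cells with predicted nuclei:
(1) cells overlapping a common nucleus are unioned, transitively;
(2) threshold-foreground not covered by any prediction is closed with a
3-px disk, filtered at 40 px (about the smallest plausible nucleus at
20× magnification), and each remaining region is appended to the unique
8-adjacent cell, dropped if adjacent to several, or promoted to a new
instance if adjacent to none; (3) uncovered nucleus pixels grow the
unique overlapping cell, or an orphan nucleus becomes a new cell.  A
second merge pass runs between (2) and (3) because a recovered region
can bridge two cells onto a shared nucleus; with it, the composite is
idempotent and leaves every nucleus pixel covered by exactly one cell.
Evaluation runs without post-processing unless explicitly enabled, so
method comparisons are not confounded by the rules.

## Evaluation protocol

Pixel-set IoU; detections truncated to the 100 top scores per image;
greedy score-ordered matching (each detection takes the unmatched ground
truth of highest IoU if that IoU reaches the threshold); precision/recall
pooled over the whole test set; 101-point interpolated AP
(`p_interp(r) = max_{r̃≥r} p(r̃)` on the grid r = 0, 0.01, …, 1); mean AP
over thresholds 0.50–0.90 in steps of 0.05.  A class with zero ground
truth has undefined AP and raises by default; a flag can exclude missing
thresholds from the mean instead.  The implementation (vectorized
running-maximum + binary search) is tested against a brute-force oracle
that builds the step curve explicitly, to 1e-12 on 200 random cases.

## Synthetic scenes

The generator emulates the benchmark's statistics rather than its optics:
star-convex cells (radial low-order Fourier perturbation of an ellipse,
radius 18–35 px at the default 256×256 frame; 14–22 px in the 128×128
desk-scale configuration), half the cells in touching clusters built by
placing centers closer than the radius sum and resolving overlap by a
radius-normalized Voronoi partition; one round nucleus per cell (6–11 px,
or 5–8 px desk-scale), a second with probability 0.05 (mitotic cells);
cytoplasm plateau 400, nucleus plateau 600, background 60, Gaussian read
noise σ = 8, and a two-pixel contact band dimmed by 25 % — the
"faint signal change" regime.  The paper-scale 64:18 train:test split is
the default write proportion.  All randomness derives from a single seed
through independent per-scene streams; geometry and rendering are pure
functions of (config, seed).  Not modelled: point-spread blur, intensity
histograms of real stains, shot noise, or a bacterial (GFP) channel —
so green tests demonstrate algorithmic correctness and trainability, not
transfer to real microscope data.

## Training

SGD with momentum 0.9, weight decay 1e-4, batch size one image, and
global gradient-norm clipping at 10 (single-image detection batches
occasionally produce loss spikes from hard proposal samples; clipping
keeps the schedule's fixed learning rates stable).  Three phases: heads +
pyramid (+fusion projections) at lr 1e-3; then backbone stages conv4 and
deeper; then everything at lr 1e-4 — with budgets 100k/250k/500k
iterations, all scalable by a single factor (the desk-scale runs use
1/1000 → 850 iterations).  The frozen nucleus branch is excluded from
every phase.  Augmentation: random crops (reflect-padded when the frame
is smaller), horizontal/vertical flips, and 90° rotations, applied
consistently to rasters, masks and boxes.

Batch normalization uses per-batch (spatial) statistics when training
from scratch: with batch size one this normalizes over H×W per channel,
which is what makes random-initialization training stable here.  When a
pretrained checkpoint supplies meaningful running statistics they can be
frozen instead (`use_batch_stats = False`), the standard small-batch
fine-tuning practice.  Grayscale-ImageNet classification pretraining is
not reproduced (it needs an external 1.2M-image corpus); backbones
initialize He-style, and `ReducedResNet.classify` provides the hook for
an optional synthetic classification warm-up.

RoI/proposal budgets are configurable; the reference configuration uses
512 RoIs per image at a 1:3 positive ratio with 1000 pre-NMS proposals,
and the desk-scale configuration (`micro_config`) uses pyramid width 128,
fc width 128, a 2-convolution mask head, 48 RoIs and 96 post-NMS
proposals — sized so one training iteration on a 128×128 scene takes a
fraction of a second on one CPU and the scaled schedule finishes in
minutes.  Ground-truth boxes are appended to the proposals during
training (standard practice; guarantees positive RoIs from the first
iteration).

## Numerical choices and degenerate inputs

Float32 tensors throughout; box coordinates are half-open
`[x0,x1)×[y0,y1)` in pixel units; decoded box sizes are clamped at
e⁴ × anchor; NMS thresholds 0.7 (RPN) and 0.5 (head); score floor 0.05
before the top-100 truncation.  Empty inputs are contracts, not errors:
an all-background image thresholds to an empty instance set, an empty
scene renders to pure background + noise, and a model on blank input
returns at most 100 (usually zero-area-filtered) detections.  Degenerate
boxes raise in RoI Align and weight-crop extraction; a zero-area box
assigns to pyramid level 2.

## Known limitations

The detector is single-class; nucleus+cell heads on a shared backbone
are out of scope.  Absolute mean-AP values of the published benchmark
require ~850k-iteration GPU training on the real 82-image dataset and
are not reproducible at desk scale; the package instead verifies the
metric arithmetic exactly on the published per-threshold operating
points and demonstrates end-to-end trainability by overfitting micro
scenes.  The parameter reduction of the backbone measured by exact tally
is 6.2×, not the ~10× sometimes quoted for this architecture family.
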