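# Methods

`membrain` is a headless, scriptable pipeline for semi-automatic semantic
and 2D instance segmentation of volume electron microscopy (vEM), built
around four stages: training-dataset construction from partially annotated
sections, 2D U-net pixel classification with transfer-learning schedules,
chunked tiled inference into viewer-loadable tile stores, and
watershed-based expansion of membrane predictions into per-cell instances.
This note records the models, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## Dataset construction from partial annotation

Annotators rarely paint a section wall to wall; they *saturate* an
arbitrarily shaped region (every contiguous pixel labeled) and stop. The
dataset builder turns `(EM image, partial label image)` pairs into
registered patch pairs whose label side is guaranteed fully annotated,
under random rotation by any angle:

1. The EM image is contrast-normalised by linear grayscale stretching.
   Anchors default to the 1st/99th per-image percentiles; the resolved
   anchor values are persisted in the dataset manifest so inference can
   apply the *same* correction. Degenerate (constant) images pass through
   unchanged.
2. For each draw, an angle is sampled uniformly from [0°, 360°); EM is
   rotated with bilinear interpolation, labels with nearest-neighbour
   (labels are categorical), and rotation-void corners are filled with the
   unlabeled sentinel (255). Rotating *before* measuring saturation is
   what makes arbitrary angles safe: void pixels can never leak into a
   patch.
3. Valid patch centres are pixels whose s×s crop window
   (rows/cols `c - s//2 … c - s//2 + s - 1`) lies entirely inside the
   saturated mask, with the image border counting as unlabeled. For odd s
   this is exactly the chessboard-distance criterion
   `distance(c) ≥ ceil(s/2)` on the Chebyshev (L∞) distance transform of
   the mask; for even s (every permitted patch size is a multiple of 128,
   hence even) the window sits half a pixel off-centre, so the equivalent
   erosion is computed with a square minimum filter of the same alignment.
   The two formulations were cross-checked against a brute-force per-patch
   scan on random masks.
4. A centre is sampled uniformly among the valid ones, the pair is
   cropped, and each configured augmentation is applied independently with
   probability 0.5: flips (applied to both images), Gaussian blur
   (σ ~ U(0.5, 2.0)), linear motion blur (length ~ U{3..15} px, random
   orientation), and histogram equalisation — the photometric ops touch
   the EM side only.

Patch sides must be multiples of 128 px so that any 1,024×1,024 tile is a
valid network input at inference time. The builder is a pure function of
(inputs, config, seed); the train/validation split defaults to 90/10.

## Ground-truth conversions

*Instance → membrane*: a pixel of instance *i* stays intracellular iff the
disk of user radius *r* around it lies wholly inside *i* (a disk keeps the
band width isotropic); eroded-away pixels become membrane. Two abutting
cells therefore share a band of width 2*r*. With `fill_ecs`, background
pixels within *r* of two distinct instances also become membrane;
remaining background maps to "other" in the 3-class scheme and to
membrane in the 2-class scheme. An instance thin enough to vanish under
erosion becomes pure membrane and logs a warning.

*Membrane → skeleton*: topology-preserving thinning
(`skimage.morphology.skeletonize`) to a 1-px medial axis; a subset of the
input, idempotent, 8-connected component count preserved. 8-connectivity
is the convention for all masks and skeletons in the package.

## The network

A standard 2D U-net: `depth` levels of double-3×3-conv + ReLU with 2×2 max
pooling, a bottleneck, nearest-neighbour 2× upsampling with skip
concatenation on the way up, a 1×1 conv head and a channel softmax.
Defaults are depth 2 and 8 base channels — deliberately small, because
the package targets desk-scale CPU training on modest ground truth; both
are configurable. Forward and backward passes are written in numpy
(im2col-style convolutions lowered to BLAS); the backward pass is verified
against central-difference gradients in float64.

Training is momentum SGD (lr 0.01–0.05, momentum 0.9) with per-pixel
cross-entropy, optional inverse-frequency class weights (EM ground truth
is typically ~75–90 % intracellular), and global gradient-norm clipping at
1.0. Clipping is load-bearing: without it a tiny CNN under momentum SGD
can blow up in the first epochs and collapse into a constant
majority-class output (dead ReLUs) from which it never recovers; clipping
removes this failure mode without affecting converged behaviour. Unlabeled
pixels (255) are excluded from loss, gradient, and accuracy.

Parameters are grouped as **encoder** (contracting path + bottleneck),
**decoder** (expanding path) and **head**; the transfer-learning modes are
per-group learning-rate multipliers:

| mode            | encoder | decoder | head | note                          |
|-----------------|---------|---------|------|-------------------------------|
| scratch         | 1       | 1       | 1    | fresh initialisation          |
| continuous      | 1       | 1       | 1    | start from pretrained weights |
| freeze_last     | 0       | 0       | 1    |                               |
| freeze_encoder  | 0       | 1       | 1    |                               |
| leaky_freeze    | 0.1     | 1       | 1    | factor configurable, (0, 1]   |
| episodic        | 1       | 1       | 1    | batches interleave old/new data (default 1:1) |

From zero velocity, one SGD step moves each parameter by exactly
`-lr_group · gradient`, which makes the leaky-freeze contract directly
testable in closed form.

### ONNX interchange

Models export to ONNX (opset 13) using Conv / Relu / MaxPool /
Resize(nearest) / Concat / Softmax nodes with float32 raw-data
initializers, and import back by structural inference (pool count → depth,
first/last conv shapes → channels and class count). The protobuf wire
codec is implemented in the package and covers the subset ONNX model files
use; round trips are exact, truncated or alien graphs raise descriptive
errors naming the offending field or op.

## Tile store and chunked inference

Volumes live on disk as per-section PNG tiles of fixed edge length
(default 1,024 px; always a multiple of 128) under a
`mip{m}/z{zzzzz}/r{rrr}_c{ccc}.png` naming scheme that is itself recorded
in a JSON-syntax `.vsvi` descriptor, so any naming dialect can be declared
rather than hard-coded. Edge tiles are zero-padded to full size; mip level
m+1 is the 2×2 block mean of level m for grayscale and a stride-2
subsample for labels. Chunked reads traverse 16-section stacks of one tile
footprint, z-innermost, then x, then y — matching the caching behaviour of
the annotation tool the store emulates.

Inference always evaluates the network on the **global tile grid** of the
input volume, regardless of request mode (whole volume, box ROI, or cubes
around anchor points): this makes the three modes agree bit-exactly on
overlaps and makes every run a pure function of (model, volume, request).
Tiles are predicted independently with no overlap or blending; border
effects at tile seams are accepted and documented rather than hidden. A
box request therefore produces the tile-aligned superset of its ROI.
Grayscale-stretch anchors must come from the training dataset; if absent,
the stretch falls back to the identity map rather than per-chunk
percentiles, which would break purity. Class maps are written as uint8
PNG tiles, probabilities quantised [0,1] → [0,255] into per-class tile
volumes, each with its own `.vsvi`; a `run.json` records the model hash,
request, and timing. At most one chunk (16 sections × one tile × classes)
is held in memory.

## Instance expansion and scoring

Membrane probability images are treated as a barrier landscape. Seeds are
the 8-connected components of the sub-threshold region (threshold 0.5)
after h-minima suppression (h = 0.1) fills spurious shallow basins; a
marker-controlled watershed floods the suppressed landscape, and ridge
pixels keep id 0 — matching the paint-until-the-border semantics of
interactive annotation. Instances below `min_area` merge into the
neighbour across the lowest-probability barrier. `seeded_fill` emulates
interactive flood filling and deliberately reproduces merge errors through
broken membranes.

Variation of information is computed from the pixel contingency table in
log base 2: `VI = H(A|B) + H(B|A)`, the two conditional terms reported
separately as merge/split error. Pixels with id 0 in *either* map are
excluded — a symmetric convention, chosen so that VI(A,B) = VI(B,A) holds
exactly; ties in categorical argmax break toward the lower class index.

## Synthetic fixtures

Voronoi mosaics of seeded cell centres are the minimal texture with
cell-like topology. Defaults: 256×256 px, 12 cells, membrane band width 3
(erosion radius ceil(3/2) = 2), intracellular gray 160, membrane gray 60,
Gaussian texture σ 10, blur σ 1. The membrane ground truth *is* the
instance→membrane conversion at the matching radius, so the triple is
exactly self-consistent. Volumes add a per-section Gaussian random walk of
the centres (step 2 px) for z-coherence; gap injection deletes membrane
along short arcs to create controlled merge errors.

Two appearance domains are used in the learning experiments: domain A is
the default rendering; domain B is brighter and lower-contrast
(cytoplasm 185, membrane 110), noisier (σ 16), with thicker membranes
(width 5). What the fixtures do **not** emulate: organelles and
intracellular texture, staining gradients, section artefacts, alignment
jitter, anisotropy — so passing tests demonstrate the machinery
(geometry, contracts, optimisation, I/O), not segmentation quality on
real tissue.

## Problem sizes in tests and the acceptance script

Training runs use 128×128 patches (the smallest legal size), 8 source
mosaics (~64 patches), a depth-2/8-channel U-net, 12–15 epochs — sizes at
which a fit takes about a minute on one CPU and the whole suite stays
within a coffee break. The transfer experiment fine-tunes on 3 domain-B
images over 5 seeds with an accuracy threshold of 0.97 and a 12-epoch
cap, comparing continuous learning against scratch epoch counts. The
augmentation benchmark trains one net per augmentation recipe per seed and
reports mean test VI with SEM over held-out images and over reseeded
retrainings.

## Known limitations

- 2D only: no 3D context, no cross-section agglomeration; instance ids
  are per-section.
- No overlap-blending at tile borders (an optional overlap mode was
  considered and deferred; conformance to the per-tile contract first).
- The ONNX importer accepts the double-conv U-net family expressed in its
  op vocabulary, not arbitrary graphs.
- The numpy training loop is single-threaded CPU; it is sized for
  fine-tuning and fixtures, not for production-scale training.
- The `.vsvi` schema here is a documented dialect: field names are chosen
  for clarity, not bit-compatibility with any specific viewer release.
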