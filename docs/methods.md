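# Methods

## Model

The network maps an N×3 point cloud to N×C class scores in four parts:
an input layer (normalized, fixed-size clouds), a training-free local
feature aggregation (LFA) layer, a stack of 1–3 dynamic segmentation
layers, and a fully connected output layer.

### Positional encoder

Coordinates are embedded per axis with sine/cosine channel pairs at
geometrically spaced wavelengths: channel pair t of axis a holds
sin(μ·a/ν^(6t/F_I)) and cos(μ·a/ν^(6t/F_I)), t = 0..F_I/6−1, and the
x, y, z blocks are concatenated. Parameters:

- **F_I** — embedding width, a multiple of 6; default 144.
- **μ** — magnitude scale; default 1000. The phase of the finest channel
  is μ·a, so μ effectively sets the finest wavelength 2π/μ relative to
  the coordinate unit.
- **ν** — wavelength base; default 100. Wavelengths grow from 2π/μ up to
  2πν^(1−6/F_I)/μ across the channel index.

The μ=1000, ν=100 defaults come from the non-parametric point-cloud
encoder lineage, which assumes coordinates normalized to a unit box. Our
scenes keep metric units (meters, extents of ~10 m), where μ=1000 puts
the finest wavelength at ~6 mm — below the sensor-noise scale — so the
fine channels behave as position hashes: they fit training scenes
perfectly and transfer poorly. The reduced synthetic benchmarks
therefore use μ=30 (wavelengths ≈0.2–6 m for F_I=24), chosen once so the
band brackets both the local structure size (trunk diameter ~0.2 m) and
the scene extent. The package defaults keep the reference values; μ is
ordinary configuration.

### Set-abstraction cascade

Stage s samples N/2^s centroids (FPS, deterministic with start index 0,
ties to the lowest index; or seeded uniform random sampling), groups
k = 64 nearest neighbors per centroid (full Euclidean sort, ties to the
lowest index), encodes each neighbor's offset from its centroid with the
positional encoder, and pools. Decisions the architecture description
leaves open, fixed here:

- **Stage count S = 3** with a full-resolution stage-0 embedding — four
  hierarchy levels in total, consistent with the printed cascade
  N→0.5N→0.25N→0.125N and with the 2160-channel output
  (F_I·(2^(S+1)−1) = 144·15).
- **Neighbor feature combination**: the neighbor's feature is
  concatenated with its centroid's feature (width 2d, achieving the
  doubling law), then modulated by the offset encoding e tiled to the
  same width: (feat + e)·e. Any translation of the whole cloud leaves
  the offsets, hence the stage features, unchanged.
- **Pooling**: element-wise max pooling plus average pooling, summed
  (not concatenated), preserving the doubling law.
- **Reconstruction**: each stage's centroid features are propagated to
  all N points by inverse-distance-weighted interpolation (power 2,
  3 nearest centroids, ε = 1e-12 guarding exact hits), and all levels
  are concatenated.

The LFA contains no learnable parameters, so per-scene feature maps are
computed once and cached for the whole of training.

### Dynamic segmentation layers

Each layer takes two feature layers (Layer 1, Layer 2). Both pass
through a Seg block — a shared per-point perceptron f → max(f/2, C) → C
with batch normalization and ReLU — yielding pre-label vectors F(n),
S(n). Choices made where the design was open:

- **Pairing normalization**: pre-labels are L2-normalized per point
  before the outer product, so M(n)[i,j] = F_i(n)·S_j(n) consists of
  cosine-similarity terms (raw-product mode retained behind a flag).
- **Pooling axis**: max pooling reduces over the Layer-1 class axis, so
  the label vector lives in Layer-2's class coordinates (Layer 2 feeds
  the downstream features). Swappable by transposing the space.
- **Volume contraction**: the N×f×C expansion re-enters the f-wide
  pipeline through a learned C→1 combination over the class axis, one
  weight vector per feature channel (a 1-wide convolution over the
  class axis). Because the expansion is an outer product, this is a
  per-channel gate: out[n,·] = feat[n,·] ⊙ (tag(n)·W + b). The gate is
  initialized near the identity (b = 1, weights ~0.1/√C) so each
  dynamic layer starts as an approximate residual block; with zero-mean
  initialization the gates start as noise and 3-layer stacks train
  markedly slower than 1-layer heads (and a single weight vector shared
  across all channels — a per-point scalar gate — leaves deep stacks
  underfitting outright).
- **Layer wiring**: the first dynamic layer pairs the LFA output with
  itself (two independent Seg blocks still give two distinct pre-label
  views); subsequent layers pair the previous layer's input (Layer 1)
  with its output (Layer 2).
- **Auxiliary pairing loss**: per point, each row of M(n) is scored
  against its diagonal index with softmax cross-entropy, averaged, and
  added with weight λ = 0.1 — maximizing real pairings and minimizing
  incorrect ones. λ = 0 switches the term off exactly.

The inverted residual block is three shared linear maps f → 2f → 2f → f
with batch normalization and ReLU between them and an additive skip;
with all-zero parameters it is exactly the identity.

## Training

Per-point softmax cross-entropy (the primary loss) plus the λ-weighted
pairing terms. Optimizer: AdamW with lr 1e-3, betas (0.9, 0.999),
eps 1e-8, weight decay 1e-4; 150 epochs and batch size 8 scenes by
default (gradients accumulate over the batch before each step).
Optional inverse-frequency class weighting (capped at 20×, off by
default) counteracts the strong class imbalance of orchard scenes,
where ground and canopy dominate and trunks/scaffolds are thin
structures; the ablation benchmarks enable it so the minority classes —
exactly the classes where local neighborhood structure matters —
contribute to the comparison. A 10% seeded validation split provides
per-epoch validation accuracy. Batch normalization uses per-scene batch
statistics during training and running estimates (momentum 0.9) at
inference.

All learnable components run on a small reverse-mode autodiff engine
over float64 numpy arrays (`dfsnet.nn`); every operator's backward rule
is verified against central finite differences, and the full dynamic
layer's gradient is checked end-to-end the same way.

## Synthetic scenes

The generator emulates single-viewpoint LiDAR scans of nursery working
scenes: a ground plane (10×10 m default), 2–3 trees — vertical
cylindrical trunks (radius 0.05–0.15 m, height 1.5–3 m) with pairwise
spacing ≥ 2 m, 2–4 ellipsoidal canopy shells, truncated-cone pots,
slanted thin scaffold stakes — plus, in complex scenes, a person
(capsule), an indicator (post + planar sign) and a miscellaneous convex
object. Points are sampled on primitive *surfaces* proportionally to
area (ellipsoid sampling is direction-uniform, a mild area bias accepted
for shells), perturbed by isotropic Gaussian noise (default sd 0.01 m),
and an azimuthal sector of each tree (default 20% of the circle, facing
away from a virtual scanner at the scene edge) is deleted to mimic
self-occlusion. Scenes are normalized to a box-corner origin; scene
sizes default to 10–60 k points. Taxonomies: complex (C=8), simple
(C=5), and a minimal 3-class set (leaves/trunks/grounds) for reduced
recovery experiments.

At zero noise the label geometry is exact (ground z = 0, trunk points on
their cylinder surface), which the tests assert. What the generator does
*not* reproduce: real foliage texture and penetration, beam divergence
and range noise anisotropy, registration artifacts, and realistic clutter
— so passing recovery tests demonstrate that the pipeline can learn
geometric class structure, not field-ready accuracy on real orchards.

## Reduced experiment sizes

The reference configuration (4096 points, F_I=144, f=2160) is exercised
for its architectural constants (feature widths, cascade sizes, output
shape). Training experiments use reduced settings chosen to fit
comfortably on a single CPU:

- **Recovery**: 20 minimal-taxonomy scenes, 1024 points, F_I=24, S=3,
  one dynamic layer; the criterion is ≥90% training accuracy within 30
  epochs.
- **Ablation benchmarks**: 16 train / 6 test scenes, 512 points,
  F_I=24, μ=30, S=3, k=16, class-weighted loss. The sampling arms use
  the simple taxonomy and 15 epochs. The depth arms use the complex
  taxonomy, 30 epochs and a 15% validation split: depth pays off on the
  harder 8-class task and needs more steps to converge, and the claim
  under study is steadier validation behavior, so the comparison is on
  mean validation accuracy over the training run. Iterate speed (ms per
  cloud) is logged for completeness but is hardware-dependent and never
  asserted.

## Known limitations

- FPS is O(N·m) per stage and k-NN grouping is a dense sort; fine at
  N = 4096, not tuned for very large scenes.
- The per-point scalar gate produced by the minimal C→1 contraction is
  a deliberately weak coupling of the label matrix into the features;
  richer contractions (per-channel weights) are a natural extension.
- mIoU averages over classes present in truth or prediction by default;
  an `include_empty` flag divides by all C instead. Reported mIoU values
  are sensitive to this choice when rare classes vanish from a test set.
- Training determinism holds up to floating-point non-associativity of
  the underlying BLAS.
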