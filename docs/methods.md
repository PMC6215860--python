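# Methods

## Problem and model

`polysyn` targets polyadic synapse detection in isotropic volumetric EM. A
synapse is modeled as one presynaptic T-bar point plus a set of postsynaptic
partner bodies; the connectome is the directed weighted graph whose edge
weight from body A to body B counts the synapses with a T-bar in A and a
partner in B. Two modeling commitments follow from the biology and are
enforced as invariants: no autapses are predicted (the host body is excluded
from the candidate set), and multiple contacts from one T-bar onto the same
body collapse to a single connection (partner body IDs are distinct within a
record).

Conventions: coordinates are 0-based (z, y, x); distances are Euclidean in
voxel units; balls and spheres are closed (distance ≤ r); intensities are
8-bit with LOW = electron-dense; label 0 means unassigned/masked; edges of
weight 0 are absent. The default voxel size is 10 nm isotropic, so radii in
voxels read directly as tens of nanometers.

## T-bar detection

**Point supervision.** Dense voxel labels are derived from point annotations:
a voxel is positive iff it lies within `positive_radius` (default 5 voxels ≈
50 nm, the scale of the T-bar platform) of an annotation.

**Voxel classifier.** A multiscale filter-bank classifier in the ilastik
tradition: per-voxel features are the raw intensity; Gaussian-smoothed
intensity, Laplacian-of-Gaussian, and gradient magnitude at σ = 1, 2, 4; and
the three sorted eigenvalues of the scale-normalized Gaussian Hessian at
σ = 2, 4. The Hessian eigenvalues are the discriminative core: a dark T-bar
platform is a blob (all three curvatures large and positive), whereas
membranes are sheets and membrane junctions are lines (one or two near
zero) — intensity-only features cannot separate a T-bar from the dark
multi-membrane junctions that otherwise dominate the false detections. A
scikit-learn MLP (one hidden layer of 32 units) classifies standardized
features. The classifier declares a receptive-field side of
2·⌈4·σ_max⌉ + 1 = 33 voxels (the support of the largest filter); tiled
inference with a one-radius context margin is exactly equal to whole-volume
inference, and inference is deterministic.

**Training.** Positive and negative voxels are sampled 1:1 (default cap
20 000 per class) to counteract the extreme class imbalance of sparse
synapse labels. One hard-negative round follows: the fitted classifier is
re-applied to the training volumes and its confident false-positive voxels
(p ≥ 0.5) join the negative pool before a refit. Rare-but-confusable
structures such as membrane junctions are underrepresented under uniform
sampling; mining them is what makes the detector precise. All sampling and
the MLP are seeded.

**Post-processing.** The probability map is Gaussian-smoothed
(`smoothing_sigma` = 2); candidates are 26-neighborhood local maxima
strictly above `confidence_threshold`; greedy NMS in descending confidence
(ties broken lexicographically) suppresses candidates within `nms_radius`
(default 10 voxels, about half the typical inter-synapse spacing).
`confidence_threshold` defaults to a deliberately conservative 0.2: smoothing
dilutes small detection blobs, the detector is tuned for high recall, and
every downstream consumer either sweeps thresholds or selects one for a
target recall (`select_threshold_for_recall`). Finally, predictions shift to
the brightest voxel within `shift_radius` (default 3): T-bar interiors are
dark and ambiguous for segmentation, and a bright nearby voxel sits safely
inside cytoplasm, so the point lands in the correct body. Ties break toward
the smallest move, then lexicographically.

## Partner prediction

**Dark-voxel masking.** Voxels with intensity < `dark_threshold` (default 60,
between the membrane and PSD intensities of the phantom and dark enough to
cover membranes in noisy data) have their segment labels set to 0 before any
candidate or interface computation.

**Candidates.** Bodies intersecting the closed ball of `candidate_radius`
(default 15 voxels ≈ 150 nm) around the T-bar, minus the host body and 0.
If the T-bar voxel itself is masked, the host is the majority non-zero label
in the radius-1 ball; if that fails the candidate set is empty and flagged.

**Interfaces.** For each dilation amount d in `dilation_amounts` (default
1…5), the interface mask is dilate(host, d) ∩ dilate(candidate, d), with
6-connected dilation applied d times, restricted to a cube of half-width
`candidate_radius` + max(d) around the T-bar. Masks are nested across
amounts by construction. Empty masks are valid (candidate absent or far).

**Features.** 27 statistics per interface × 5 interfaces = 135 values, every
slot named (`polysyn.psd_predict.feature_names()`): voxel count and
log(1+count); mean/std/min/max/median intensity; 8 histogram-bin counts
(32-wide bins over [0, 255]); counts below 4 darkness cutoffs (0.5×, 1×,
1.5×, 2× the dark threshold) and the dark fraction (count below 1× / count);
centroid-to-T-bar distance; bounding-box extents (z, y, x); fraction of the
mask within `candidate_radius` of the T-bar; surface-voxel count (6-neighbor
outside the mask, with voxels outside the region of interest counting as
outside) and its ratio to the count. Empty masks contribute an all-zero
block, with min/max/median conventionally 0. Feature extraction is invariant
to global translation of the scene.

**Classifier.** Standardized features feed an MLP with a single hidden layer
of 50 units trained with cross-entropy (seeded, deterministic at inference).
Training pairs come from ground-truth records: every candidate body of every
annotated T-bar is one example, positive iff it is a ground-truth partner,
with partner bodies resolved as the masked label at the brightest-voxel-
shifted PSD point (falling back to the stored body ID). Diagnostics count
ground-truth partners that fall outside the candidate set.

**Segmentation awareness.** The interface features depend on the error
behavior of the segmentation (boundary jitter moves interfaces off the true
membrane), so the partner model must be trained on the same *kind* of
segmentation it will be applied to. `train_partner_model` therefore accepts
multiple (volume, labels, records) sets; the test protocol fits one model
against clean segmentations and one against corrupted ones and applies each
to its own kind.

## Pipeline and confidences

The end-to-end run is: probability map → point extraction → optional
threshold selection for a target T-bar recall (default target in the
evaluation config: 0.9) → brightest-voxel shift → partner prediction per
T-bar → graph construction → metric report. The confidence stored on a
predicted (T-bar, partner) pair is min(T-bar confidence, partner score):
both stages produce calibrated-enough scores in [0, 1], the min is monotone
in each, and a single sweep over pair confidences can then prune weak T-bars
as well as weak partners. The pipeline itself is deterministic; all
randomness lives in training and is seeded.

## Evaluation machinery

One-to-one T-bar matching is greedy by ascending pairwise distance among
pairs within `max_distance` (default 27 voxels ≈ 270 nm) and, optionally,
within the same segment; an optimal-assignment variant is available behind a
flag (`optimal=True`) but the greedy scheme is the default for determinism
and transparency. Synapse-level PR counts each (T-bar, partner body) pair as
one unit. Graph-level metrics (weighted, thresholded, asymmetric,
connections added/missed) are defined in the README; all use the convention
that an empty denominator yields 1 (no claims, no errors), except the
added/missed normalization, which is 0 when no strong ground-truth edges
exist (keeping normalized-missed + asymmetric recall = 1). Thresholds t, t₁,
t₂ are synapse counts ≥ 1, with t₁ ≥ t₂ (equality is the symmetric case).

Orphan filtering removes predictions whose presynaptic or postsynaptic body
is an orphan (a segment hosting neither a ground-truth T-bar nor a shifted
ground-truth PSD point) before precision is computed; ground truth and hence
recall denominators are untouched. Undirected views sum antiparallel edge
weights (the max is the other defensible choice; sum was chosen so that
total weight is conserved). When ground truth is evaluated against a
*different* segmentation (e.g. the corrupted one), partner bodies are
re-resolved through it via the shifted PSD points; partners that collapse
onto the host body are autapses under that segmentation and are dropped from
the ground-truth pair set, mirroring the no-autapse rule.

The body-proximity baseline samples boundary contacts (face-adjacent voxel
pairs with different non-zero labels) uniformly with replacement and assigns
each a direction by fair coin. Its operating curve is traced by sweeping an
edge-weight cut on the accumulated graph, since its weights are sample
counts rather than classifier confidences.

## The phantom generator

The generator emulates exactly the data features the pipeline depends on:
bodies from a seeded nearest-seed (Voronoi) partition (default 20 bodies in
128³); dark membranes (intensity 30) against bright cytoplasm (150); T-bar
motifs (platform + pedestal, intensity 20) with a halo of vesicle-like rings
(60) inside a host body; PSD patches (80) darkening the partner-side face of
the membrane; Gaussian intensity noise (σ = 10); and a "predicted
segmentation" variant with boundary jitter (2 growth passes), 2 random plane
splits, and 2 random adjacent merges. Intensities are ordered T-bar <
membrane < vesicle < PSD < cytoplasm, mirroring electron density, and are
chosen so the defaults are learnable by the desk-scale classifiers without
being trivial (membrane vs T-bar differ by less than one noise standard
deviation per voxel). Synapses (default 15 per phantom) sit ≥ 3 voxels from
the volume border, within 6 voxels of a membrane, with 1–4 partners drawn
from distinct neighboring bodies reachable within the candidate radius, and
with pairwise T-bar spacing ≥ 20 voxels (twice the NMS radius) so
suppression cannot merge distinct ground-truth synapses. Everything is
reproducible from one seed.

What the phantom does **not** emulate — organelles (mitochondria,
microtubules), anisotropy, staining gradients, imaging artifacts, realistic
neurite geometry, and realistic segmentation failure modes beyond
jitter/split/merge. Passing the phantom tests therefore demonstrates that
the pipeline machinery is correct and that the two-stage design recovers
planted structure under noise and segmentation corruption; it does not
certify performance on real tissue.

## Problem sizes and test protocol

The test suite trains the voxel classifier on one 128³ phantom (~15 000
balanced voxel samples, one hard-negative round) and the partner MLP on
pairs pooled over four phantoms (~130 examples), then evaluates end to end
on a held-out fifth phantom, against both its clean and its corrupted
segmentation. Metric implementations are checked exactly against independent
brute-force enumeration on 1000 random graph pairs (12 nodes, weights ≤ 15),
and the geometric primitives against brute-force enumeration on small random
volumes. The whole suite runs in a few minutes on one CPU.

## Known limitations

- The voxel classifier is a filter-bank model with a fixed receptive field;
  it has no learned spatial hierarchy and will underperform a trained CNN on
  textures it cannot express through the bank.
- The 135-feature composition is one defensible instantiation of
  interface-pooled statistics; slots are documented and stable but not
  claimed optimal.
- Partner candidates are limited to the sphere radius; partners reachable
  only beyond it are invisible to both training and prediction (the
  training diagnostics report such cases).
- The matcher's greedy assignment can differ from the optimal assignment in
  dense scenes; the optimal variant is provided for checking.
- Volumes are processed in memory (tiled inference bounds peak memory for
  features, but the volume itself is not streamed).
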