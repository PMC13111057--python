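# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices, and the design decisions that were genuinely open.

## Skeleton graph

The scheme fixes 17 lateral-view keypoints: 1 Nose, 2 Between the ears,
3 Neck base, 4 Shoulder midpoint, 5–7 left forelimb (base, knee, hoof),
8–10 right forelimb, 11–13 right hindlimb, 14–16 left hindlimb, 17 Tail
root. The 16 edges form a spanning tree: the head–neck chain (1–2–3–4), two
forelimb chains off the shoulder midpoint, the trunk axis (4–17), and two
hindlimb chains off the tail root. This anatomical tree matches the region
grouping of the keypoints (head / trunk / four limbs / tail); with 17 nodes
any 16-edge connected graph is necessarily a tree, so no cycles exist and
message passing reaches every joint.

**Partitioning.** Spatial convolutions split every joint's 1-neighborhood
into K_v subsets, one adjacency matrix each:

- `uniform` (K_v = 1): A + I;
- `distance` (K_v = 2): root vs. 1-hop neighbors;
- `spatial-configuration` (K_v = 3, default): root / centripetal /
  centrifugal. Centripetal means the neighbor is closer to the trunk than
  the joint itself. Closeness is *hop distance in the skeleton tree* to the
  nearest of the center joints {4, 17}: the scheme carries no coordinates,
  and on a tree the hop distance to the trunk axis is the coordinate-free
  analogue of distance to the gravity center. Ties go to the root subset.

In every strategy the partition matrices tile the neighbor set exactly:
Σ_k A_k = A + I.

**Normalization.** Each partition matrix is symmetrically normalized,
Ā = D^{-1/2} A D^{-1/2} with D the diagonal degree matrix. Zero-degree rows
(possible for isolated partitions or fully occluded joints) map to zero rows;
an ε = 1e-6 guard keeps the inversion finite. The largest eigenvalue of the
normalized uniform matrix is ≤ 1, so message magnitudes cannot blow up with
depth.

**Temporal edges** connect the same joint in frames t and t+k for
k = 1..k_max. The reach k_max defaults to 1 (consecutive frames); it is a
config field because larger strides are plausible but there is no evidence
one is needed — the 9-tap temporal convolution already spans ±4 frames.

## Data pipeline

Input is the DeepLabCut CSV dialect (three header rows; x, y, likelihood per
bodypart) or an equivalent HDF5 table. Bodyparts are matched by name and
reordered to scheme order, so column order in the file is irrelevant.

- **Confidence filter** (default threshold 0.6, the usual keypoint
  reliability cutoff): keypoints below threshold get the per-frame
  trunk-center coordinates and confidence 0. Trunk-center imputation keeps
  tensors dense without inventing motion; the zeroed confidence channel
  tells the network the coordinates are imputed.
- **Windowing**: clips are loop-padded (shorter) or uniformly subsampled at
  indices round(i·L/T) (longer) to a fixed window, default 150 frames = 6 s
  at 25 fps, matching typical clip durations.
- **Normalization**: per-frame translation puts the midpoint of joints 4 and
  17 at the origin; one global scale per clip makes the median trunk length
  1. The transform is idempotent and invariant to image translation and
  uniform scale, which removes camera-geometry nuisance without touching
  posture.
- **Split**: 7:2:1 train/val/test by largest-remainder apportionment over a
  seeded permutation of the *sorted* ids — deterministic for a seed and
  independent of input order. The splitter is global rather than stratified
  by default (published per-class counts are not exactly 7:2:1 per class);
  a stratified mode exists behind a flag. 18,690 items yield exactly
  13,083 / 3,738 / 1,869.
- **Augmentation** operates on keypoint tensors, never on the topology: the
  joint ordering, edge set, shape and label are invariant. Random occlusion
  zeroes the confidence of a joint subset in one contiguous temporal block;
  joint erasure zeroes whole joints; background disturbance adds a shared
  low-frequency sinusoidal drift to all joints (camera/background motion);
  Gaussian noise perturbs coordinates i.i.d. Dataset expansion keeps the
  original as the first copy and appends factor−1 augmented variants
  (default factor 3: 6,230 → 18,690).

## BC attention

One shared coefficient pass per layer: features are averaged over frames
(V×F per clip; this keeps attention O(V²) and reflects that posture, not
instantaneous jitter, should set the topology), lifted by a learned map W to
F′ = the layer's output channels, scored by
e_kl = LeakyReLU(aᵀ[Wh_k ∥ Wh_l]) (slope 0.2), and normalized row-wise by
softmax into α.

- **Local matrix B_k** = α masked to partition k's support, rows
  renormalized over the surviving entries (empty rows stay zero). It
  modulates the strength of physical edges.
- **Global matrix C** = α hard-thresholded at C_λ; entries are kept only if
  strictly above the threshold, so thresholding is idempotent and the number
  of surviving edges is monotone non-increasing in C_λ. C_λ defaults to 1/V:
  a uniform attention row contributes nothing, so only above-uniform links
  become new edges. C is *not* renormalized after thresholding — the
  threshold is a sparsifier, and renormalizing would re-inflate rows that
  were deliberately emptied.

The fused convolution is f_out = Σ_k W_k(f_in(Ā_k ⊙ B_k ⊙ M_k + C)):
multiplicative local modulation on the physical graph plus additive global
edges. Setting B = 1, C = 0, M = 1 recovers the plain form exactly, which is
the ablation axis — the network exposes it as a runtime switch
(`set_attention_enabled`), and a single shared α feeds both matrices because
the attention coefficients are defined once per layer. B and C are
recomputed every forward pass from current features, so they train jointly
with the convolution weights.

## Backbone

Input batch normalization over the C×V channel pairs, then the unit stack,
global average pooling over frames and joints, and a fully connected head.
Each unit: spatial conv → BN → ReLU → temporal conv (kernel 9×1, zero
padding 4, stride 1 or 2) → BN → residual add → ReLU → dropout 0.5. The
residual is the identity when shape permits, otherwise a strided 1×1
projection. Output frames per unit: ceil(T/stride).

The default plan is ten units, channels
(64, 64, 64, 64, 128, 128, 128, 256, 256, 256), temporal stride 2 at units
5 and 8 — three constant-width blocks, which is what makes layers inside a
block isomorphic and hence prunable. The published architecture never prints
its widths, so parameter and FLOP totals of this plan (3.29 M / 2.22 M after
pruning; 5.71 / 4.16 GFLOPs at T = 150) characterize *this* configuration;
the counting utilities are exact for any config. The default prune set is
{7, 9} (the layers identified as isomorphic with their predecessors; an
alternative reading names {3, 5}, so the set is a config field). Pruning
refuses width-changing or striding layers — removing those would break the
channel chain or the frame-rate schedule.

FLOP accounting counts multiply-accumulates ×2 over the spatial mixing,
channel transforms, temporal convolutions, residual projections, attention
lifts and the head; elementwise normalization and activations are excluded.
`count_flops` returns raw FLOPs (its smallest meaningful unit — a V→1 dense
map is 2V FLOPs); divide by 1e9 for GFLOPs.

## Training

SGD with momentum 0.9, initial learning rate 0.1, weight decay 5e-4, batch
size 64, cross-entropy loss, dropout 0.5 — the published recipe. (The
source's table and text disagree on weight decay, 5e-4 vs 1e-4; the table
value is the default and the field is configurable.) The schedule is
unstated beyond the initial rate; the default decays ×0.1 at epochs 40 and
80, the conventional two-step policy for 100-epoch SGD. Argmax ties break
toward the lowest class index (numpy convention). Training is deterministic
for a fixed seed under single-threaded numpy.

The whole stack — including a reverse-mode autodiff core with
broadcast-aware primitives, fused batch-norm/spatial-conv/temporal-conv ops
and a no-grad inference mode — is float64 numpy. Backprop is validated
against central finite differences (≤1e-3 relative on every parameter group
of a full model). Memory per training batch is dominated by retained
activations (float64, ~10 full-size arrays per unit); the CLI therefore
defaults to a CPU-sized four-unit stack (32, 32, 64, 64) and leaves the full
ten-layer plan to an explicit config.

## Metrics

Accuracy is pooled (trace of the confusion matrix over its total — for the
binary case this is (TP+TN)/(TP+TN+FP+FN)). Precision TP/(TP+FP) and recall
TP/(TP+FN) are computed one-vs-rest per class and macro-averaged; the
averaging mode behind the published single values is unstated, so macro is
the default (class-balanced, the usual reporting choice) with micro behind a
flag. F1 is the harmonic mean of the macro precision and recall. Classes
with zero denominators are excluded from the macro mean with a warning.
Keypoint localization error is RMSE in pixels, per keypoint and pooled.
All implementations are cross-checked against scikit-learn to 1e-9 in the
tests; sklearn is the oracle, never the implementation.

## Synthetic data

The generator renders what the classifier assumes: lateral-view 2D
17-keypoint clips at 25 fps with per-joint confidences. Behavior templates
are base poses (pixel coordinates in a 1920×1080 frame) plus sinusoidal
oscillators:

- *walking*: diagonal-couplet gait (LF+RH vs. RF+LH in antiphase) at 1.5 Hz,
  knee/hoof amplitudes 15/30 px, forward drift 60 px/s, slight head bob;
- *feeding*: head chain lowered to the ground, vertical oscillation at 1 Hz
  (nose 14 px, attenuating up the chain), trunk static;
- *lying*: low-silhouette static pose, limbs extended;
- *sitting* (dog-sit): hindquarters lowered, forelimbs vertical, head up,
  static.

Defaults: 50 clips per class, T = 150 frames, coordinate noise σ = 3 px
(comparable to a well-trained pose estimator's localization error),
confidence ~ N(0.95, 0.04) clipped to [0, 1], and a 5% per-joint chance of
one contiguous occlusion window (confidence 0) per clip. Per-sequence seeds
derive from `SeedSequence(seed, spawn_key=(class, index))` — disjoint and
platform-stable. Bone lengths along all 16 edges vary < 20% within any
noise-free clip, and oscillator frequencies sit well below the 12.5 Hz
Nyquist limit.

What the generator does *not* emulate: perspective and camera motion,
pose-estimator failure modes that are correlated across joints, behavior
transitions within a clip, multiple animals, and class overlap — real
feeding-vs-rooting distinctions are far subtler than these templates. A
nearest-centroid classifier on time-averaged normalized poses already
achieves 100% on noise-free data; that is by design (it guarantees the
learning-sanity check is a test of the training machinery, not of the
task's difficulty), and it means passing accuracies here say nothing about
accuracy on real barn video.

## Problem sizes in the checks

The learning-sanity check trains a two-unit (8, 16)-channel network on 200
clips of 75 frames for 30 epochs — small enough to run in minutes on one
CPU while still exercising attention, batch norm, striding, residuals and
the full SGD recipe. The dense-oracle comparisons run at V ≤ 17, where
brute-force per-frame matrix products are exact and fast.

## Known limitations

- 2D lateral view only; no 3D skeletons and no variable keypoint counts.
- Single animal per clip; no tracking or multi-pig batching.
- The pose estimator itself is out of scope: the package consumes its
  output format and quantifies its error (keypoint RMSE), nothing more.
- Published headline accuracies were measured on an unreleased video
  corpus; nothing here reproduces them, and the synthetic results should
  not be compared against them.
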