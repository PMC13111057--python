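# bcstgcn

Skeleton-based recognition of pig behaviors — feeding, walking, lying, and
the clinically significant dog-sitting posture — from 2D keypoint tracks, for
precision-livestock researchers who already run a pose estimator (e.g.
DeepLabCut) over barn video and want behavior labels per clip rather than raw
coordinates.

## The model

A pig is represented as a spatiotemporal graph `G = (V, E)`: 17 anatomical
keypoints per frame (nose … tail root), 16 skeleton edges within each frame,
and temporal edges joining the same keypoint across frames. A clip is a
tensor `(N, C=3, T, V=17)` holding x, y and the pose-estimator confidence per
joint and frame.

The backbone is a spatiotemporal graph convolutional network (ST-GCN). Each
unit applies a partitioned spatial graph convolution

    f_out = Σ_k  W_k ( f_in ( Ā_k ⊙ M_k ) ),     Ā_k = η^{-1/2} A_k η^{-1/2}

(K_v = 3 partitions: root / centripetal / centrifugal relative to the trunk
axis; `M_k` learnable edge importance), followed by a 9-tap temporal
convolution, a residual connection and dropout. Stacked units feed global
average pooling and a softmax classifier.

Two additions define **BCST-GCN**:

1. **BC module** — a self-attention pass
   `e_kl = LeakyReLU(aᵀ[W h_k ∥ W h_l])`, `α = softmax(e)` reconstructs the
   graph every forward pass. A *local* matrix `B_k` (α masked to each
   partition's first-order neighborhood and row-renormalized) modulates the
   physical edges, while a *global* matrix `C` (α hard-thresholded at `C_λ`)
   adds non-physical edges between joints that move together, e.g. head and
   forelimbs during rooting. The spatial convolution becomes

       f_out = Σ_k  W_k ( f_in ( Ā_k ⊙ B_k ⊙ M_k + C ) ).

2. **Layer pruning** — layers inside the constant-width blocks of the default
   ten-layer plan are isomorphic with their predecessors; removing them
   (default set {7, 9}) strictly reduces parameters and FLOPs while
   preserving the output contract.

Because no public pig keypoint corpus exists, the package ships a synthetic
generator that renders lateral-view 17-keypoint clips at 25 fps for the four
behaviors (diagonal-couplet walking gait, head-bobbing feeding, low-profile
lying, rear-lowered sitting), with coordinate noise, confidence scores and
occlusion windows, so every stage is testable end to end.

Everything runs on plain numpy: a compact reverse-mode autodiff core
(`bcstgcn.autodiff`) provides the training machinery, validated against
finite differences.

## Worked example

```python
import numpy as np
import bcstgcn as bg

# simulate a labeled corpus: 50 clips per behavior, 3 s at 25 fps
cfg = bg.SimulationConfig(n_per_class=50, T=75, seed=0)
seqs = [bg.normalize_coordinates(s) for s in bg.simulate_dataset(cfg)]
split = bg.split_dataset([s.source_id for s in seqs], seed=0)
by_id = {s.source_id: s for s in seqs}
train = [by_id[i] for i in split.items("train")]
test = [by_id[i] for i in split.items("test")]
print(f"split sizes: {split.sizes}")

X = np.stack([s.data for s in train])
y = np.array([s.label for s in train])
clf = bg.BCSTGCNClassifier(channels=(8, 16), stride_layers=(2,),
                           epochs=30, lr_steps=(20,), random_state=0)
clf.fit(X, y)
print(f"trainable parameters: {clf.n_parameters_:,}")

X_test = np.stack([s.data for s in test])
y_test = np.array([s.label for s in test])
report = bg.evaluate(y_test, clf.predict(X_test), labels=sorted(set(y_test)))
print(f"held-out accuracy:  {report.accuracy:.3f}")
print(f"macro precision:    {report.precision:.3f}")
print(f"macro recall:       {report.recall:.3f}")
```

prints

```
split sizes: (140, 40, 20)
trainable parameters: 5,728
held-out accuracy:  1.000
macro precision:    1.000
macro recall:       1.000
```

The 7:2:1 split apportions the 200 clips to 140/40/20. A two-unit network
with 8 and 16 channels (5,728 trainable scalars) separates the four synthetic
behaviors perfectly on the held-out clips after 30 epochs of SGD — the
classes differ in static pose and gait, and a nearest-centroid oracle
(`bg.nearest_centroid_predict`) confirms the task is linearly separable
before any training is credited.

`BCSTGCNClassifier` follows the scikit-learn estimator contract
(`get_params` / `set_params` / `clone`, fitted attributes `classes_`,
`model_`, `history_`), so it composes with sklearn model selection.

## Command line

```sh
bcstgcn simulate --out data --n-per-class 50 --seed 0   # DLC CSVs + labels.tsv
bcstgcn train    --data data --out model.npz --epochs 30
bcstgcn eval     --data data --model model.npz --out metrics.tsv
bcstgcn ablate   --data data --out ablation.tsv          # baseline / +BC / +BC+prune
bcstgcn inspect-graph --model model.npz --data data --out graphs/
bcstgcn summary  --model model.npz                       # parameters + GFLOPs
```

`train` reads any directory of DLC-format CSVs (3 header rows:
scorer/bodyparts/coords) with a two-column `labels.tsv` manifest, applies the
0.6 confidence filter, windows clips to a fixed length, and normalizes
coordinates. The CLI's default stack is CPU-sized; set `channels` /
`stride_layers` in a YAML `--config` for the full ten-layer plan.

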