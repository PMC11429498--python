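# Methods

## Problem setting

The package detects abnormal behavior in single-housed laboratory mice
from 2-D keypoint trajectories. Abnormal behavior cannot be enumerated
in advance, so no abnormal samples are used for training: an encoder is
fit to classify four *normal* behaviors, and test clips whose embeddings
join no density cluster of the normal repertoire are flagged abnormal.

## Data model

A recording is a rank-5 tensor `(N, C, T, V, M)`: clip, channel, frame,
joint, animal. `C = 3` with channels `x`, `y` (image-plane pixels,
origin top-left) and `conf` (tracker likelihood in [0, 1]); `V = 12`
mouse joints (nose, head, ears, neck, forepaws, spine midpoint,
hindpaws, tail base, tail tip); `M = 1`. Recordings are cut into
non-overlapping 50-frame clips (the trailing remainder is dropped so all
clips batch uniformly).

Preprocessing: coordinates are mapped to [−1, 1] by centering on the
frame midpoint and dividing by half the larger frame dimension (aspect
ratio preserved; the frame size is kept as metadata so pixel-denominated
augmentation stays in pixel units). Before encoding, each clip is
rigidly aligned to its initial egocentric frame: the spine midpoint
(averaged over the first 5 frames) moves to the origin and the
tail-base → neck axis (same average) rotates onto +x. The transform is
shared by all frames of a clip, so within-clip translation, rotation and
posture change are fully preserved while arbitrary arena position and
heading are removed. This is standard practice in pose-based behavior
analysis; without it, an encoder trained on a few hundred clips spends
its capacity memorizing absolute position. The 5-frame reference average
suppresses per-frame keypoint jitter in the alignment itself, which
otherwise injects angle noise that disperses the embeddings of
fast-translating clips.

## Skeleton graph

The joint graph is a tree of 11 anatomically plausible edges over the 12
joints (nose–head, head–ears, head–neck, neck–forepaws, neck–spine,
spine–hindpaws, spine–tail base, tail base–tail tip), configurable.
`A = I + E` (self-loops included so no joint has degree zero), `Λ` its
diagonal degree matrix, and the convolution operates on the symmetric
normalization `Λ^{-1/2} A Λ^{-1/2}`. Two partition strategies are
provided: `uniform` (one matrix) and the default `distance` (self-loop
part and neighbor part, normalized with the shared `Λ` so the stack sums
to the uniform matrix). Spatial-configuration (3-way) partitioning is
out of scope — it needs a root joint the skeleton does not distinguish.

## Encoder

Per block: spatial graph convolution → batch norm → ReLU → SE gate →
temporal stage → batch norm → +residual → ReLU.

- **Spatial stage.** For each partition `k`, the joint-mixing matrix is
  `(Â_k + G) ⊙ M_k`, followed by a 1×1 channel-mixing convolution; the
  partition results are summed. `M_k` is a learnable elementwise mask
  initialized to ones (one per partition). The noise matrix `G = Λ·φ`,
  `φ_ij ~ N(μ, σ²)` i.i.d., is shared across channels and frames within
  one forward pass, resampled per training batch, and disabled at
  inference; entries in row `i` have standard deviation `Λ_ii σ`. `σ`
  is interpreted as a standard deviation (defaults `μ = 0`,
  `σ = 0.05`); `σ = 0` degenerates to the deterministic `μ`-scaled
  degree matrix and, with `μ = 0`, to the exact noise-free path.
- **SE gate.** `z_c` = global mean of channel `c` over time × joints;
  gate `s = sigmoid(W₂ ReLU(W₁ z))` with a bottleneck of ratio `r = 4`
  (the channel widths here are small; `r` must divide the width). The
  gate multiplies each channel, so it can only attenuate: zero weights
  give exactly `0.5 · input`. The expand weights are `(C, C/r)` — the
  only shape for which the two-layer bottleneck closes.
- **Temporal stage.** Default is the six-branch form: an entry 1×1 conv
  maps to the block width (must be divisible by 6), split into six equal
  groups processed by a 1×1 conv, a window-3 max pool (same padding),
  and kernel-3 convolutions at dilations 1–4; outputs are concatenated
  and remixed by an exit 1×1 conv. At stride 1 time length is
  preserved, at stride 2 halved (ceil). The single-branch fallback (and
  the baseline when the multi-branch toggle is off) is a kernel-9
  temporal convolution; the six-branch stage has strictly fewer
  parameters at equal width (≈ 2.4 C² vs 9 C²).
- **Residual** is the identity when shapes match, otherwise a strided
  1×1 conv + batch norm.

A model is an input batch norm over channels, the block stack (default
plan 64×3–128×3–256×3 with temporal stride 2 at width changes; the
desk-scale experiments use 12–24 with one stride-2 stage), global
average pooling over time, joints and animals to one embedding per clip
(length = final width), and a linear softmax head. With the noise, SE
and multi-branch toggles all off the model is the plain spatio-temporal
graph-convolutional baseline, verified bitwise in the tests.

All tensors are float32 by default (float64 for gradient checking).
Gradients come from a small reverse-mode autodiff over NumPy
(`abnet._autograd`) with hand-written vector-Jacobian products, checked
against central finite differences end to end.

## Training

SGD with momentum 0.9, weight decay 1e-4, cross-entropy loss; initial
learning rate 0.1, batch size 64, 100 epochs, with per-clip augmentation
of training batches only: one scale drawn uniformly from [0.97, 1.03]
and one (dx, dy) shift from ±5 px, converted to normalized units via the
stored frame scale. The default schedule decays ×0.1 at epochs 40/80; on
the desk-scale benchmark (200 clips) the model is still underfit at
epoch 40, so the benchmark uses a single decay at epoch 80 of 100. All
randomness (initialization, batch order, augmentation, adjacency noise)
flows from one seed; runs are bit-reproducible.

Two practical notes. Batch-norm statistics degrade when the last batch
of an epoch is much smaller than the rest; benchmark batch sizes are
chosen to divide the training-set size. And the top-k accuracy metric
breaks probability ties by ascending class index for reproducibility.

## Anomaly detection

Embeddings of the evaluation clips are reduced by PCA and clustered with
DBSCAN; clips in no cluster are abnormal. Choices:

- **Whitened PCA, 4 components** (defaults; both configurable, capped at
  the data rank). DBSCAN uses a single global radius, which presumes
  comparable scale in every direction; whitening (unit variance per
  retained component) provides that. Four components match the
  complexity of a small behavior repertoire; higher whitened dimensions
  re-amplify noise directions and blur the cluster/outlier margin.
- **DBSCAN, `min_samples = 5`,** written in-package so that border
  points deterministically join the cluster of their lowest-index core
  neighbor and cluster ids are numbered by first occurrence — the
  labeling is a pure function of the point set, independent of input
  order. Verified against a brute-force density-reachability closure
  and against scikit-learn's core/noise sets.
- **Radius heuristic.** `eps` = median of the `min_samples`-NN distances
  (self included) × 2.5 unless set explicitly. The ×2.5 margin keeps
  legitimately diffuse behavior clusters intact; the k-NN definition
  makes `score ≤ eps` exactly the core-point condition.
- **Continuous score.** The binary flag has no natural threshold sweep,
  so the distance to the `min_samples`-th nearest neighbor in reduced
  space serves as the anomaly score for precision–recall analysis, with
  the DBSCAN flag as its operating point. Average precision is computed
  as the step-wise sum of precision × recall increment over the ranked
  scores, ties grouped into one threshold (cross-checked against
  scikit-learn).

A caveat worth knowing: whitening is fit on the evaluation set, so an
anomaly contingent large enough to dominate a variance direction would
compress its own outlierness. At the planted-anomaly fractions used
here (≈ 11% of the evaluation set, scattered across three families)
this does not occur.

## Synthetic data

No public dataset accompanies the method, so the generator is
first-class. A top-view template skeleton (invented proportions,
~88 px nose-to-tail in a 640×480 frame) is animated per class:

- *movement* — centroid translates along a fixed heading at 4 px/frame;
- *head turning* — body static; nose/head/ears rotate about the neck in
  a sinusoid of amplitude 1.1 rad;
- *standing* (rearing against a barrier) — static centroid; anterior
  joint offsets foreshorten by up to 45% over a ramp;
- *turning* — the whole body heading advances at 0.05 rad/frame.

Anomaly families: *freeze* (static centroid, 6 px high-frequency
tremor), *jump* (heavy-tailed Student-t(1.5) centroid steps, scale
18 px, clipped), *limb* (one forepaw decoupled, random-walking away
from the body frame). Everywhere: i.i.d. Gaussian observation jitter
(sd 1 px — typical tracker error; temporal smoothness comes from the
kinematics, not the noise) and Beta(9, 1) confidence values. Values are
fixed once as plausible for a 0.5 m arena filmed at 640×480 and ~30 fps.

Datasets are split stratified 8:2 (the benchmark uses 5:6 per class to
get round 50/10 counts); anomalies appear only in the test split,
matching the semi-supervised protocol. Generation is a pure function of
the seed.

What the generator does *not* emulate: gait articulation, occlusion and
identity switches, tracker dropouts (conf is uniformly high), arena
walls constraining trajectories, and the long-tailed diversity of real
abnormal behavior. Passing the synthetic benchmark therefore shows the
pipeline is correct and that well-separated kinematic anomalies are
recoverable — not that real mouse pathology would be detected at the
same rates.

## Benchmark and problem sizes

The standard benchmark (`abnet.benchmark`) uses 50 training and 10 test
clips per class (200/40) of 50 frames, five planted anomalies (2 freeze,
2 jump, 1 limb) in the test split, a 12/24-channel two-stage encoder
(stride 2 at the width change), batch 50, 100 epochs with one decay at
epoch 80 — about one minute per seed on one CPU. With defaults it
reaches perfect held-out classification and flags exactly the planted
anomalies (AP 1.0) on seeds 0–4; the acceptance suite requires AP ≥
0.95 with exact flags in at least 4 of 5 seeds.

The overfit check uses 20 noiseless movement/standing clips and a
16-channel three-stage encoder with noise and SE active and the
kernel-9 temporal stage (16 is not divisible by 6, so the six-branch
stage — exercised separately by the layer oracles — is switched off
there).

## Known limitations

- Single animal only (`M = 1`); no multi-animal pooling or tracking.
- No learned adjacency; the graph is fixed apart from the edge mask and
  the training-time noise.
- Missing detections are carried as-is (low conf), not interpolated.
- The anomaly stage is transductive over the evaluation set (PCA,
  radius heuristic and clustering are fit on it); the sklearn-style
  detector additionally supports fitting on one set and scoring
  another via the stored reduction.
- CPU-bound NumPy training limits practical model sizes to the
  desk-scale plans used here.
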