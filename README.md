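# abnet

Skeleton-based behavior classification and semi-supervised
abnormal-behavior detection for laboratory mice.

Quantifying abnormal behavior in mice is central to behavioral assays in
neuroscience, pharmacology and toxicology, but abnormal behavior resists
supervised treatment: it is hard to define in advance and abnormal
training samples are scarce. `abnet` takes the semi-supervised route —
learn an encoder of *normal* behavior only, then flag whatever falls
outside all learned behavior clusters:

1. **Encode.** Keypoint trajectories (12 mouse body parts from a
   DeepLabCut-style tracker, arranged as an `(N, C, T, V, M)` tensor with
   channels `x, y, conf`) pass through an enhanced spatio-temporal
   graph-convolutional encoder. Per block, the spatial stage computes

   `y = Ω₁ₓ₁( X · ((Λ^{-1/2} A Λ^{-1/2})_k + G) ⊙ M_k )`, summed over
   partitions *k*,

   where `A` is the joint adjacency with self-loops, `Λ` its degree
   matrix, `M_k` a learnable edge-importance mask, and `G = Λ·φ` with
   `φ ~ N(μ, σ²)` a Gaussian perturbation resampled each training pass
   that creates transient links between non-adjacent joints. A
   squeeze-and-excitation gate (`s = σ(W₂ ReLU(W₁ z))`, `z` the global
   channel mean) recalibrates channels, and a six-branch temporal stage
   (1×1 conv, window-3 max pool, kernel-3 convs at dilations 1–4 over
   equal channel groups) replaces the single kernel-9 temporal
   convolution at a fraction of its parameters. Each block is trained
   with batch norm, a residual connection and ReLU; global average
   pooling yields one fixed-length behavior embedding per clip, and a
   softmax head classifies the normal behaviors (movement, head turning,
   standing, turning) during training.
2. **Detect.** Embeddings of held-out clips are reduced by whitened PCA
   and clustered with DBSCAN. Clusters are the normal behaviors; any
   clip in no cluster is flagged abnormal. A continuous anomaly score
   (distance to the `min_samples`-th nearest neighbor in reduced space)
   supports precision–recall analysis; `score ≤ eps` exactly
   characterizes DBSCAN core points.

Everything runs on a single CPU: the network, its gradients and the SGD
loop are implemented directly on NumPy with an in-repo reverse-mode
autodiff engine, verified against finite differences and brute-force
layer oracles in the test suite.

## Worked example

Because no public mouse keypoint dataset accompanies the method, the
package ships a synthetic generator whose four normal classes and three
anomaly families (freezing with tremor, erratic jumps, limb
dissociation) have controlled kinematics. The full pipeline, from the
library:

```python
from abnet.benchmark import run_anomaly_benchmark

res = run_anomaly_benchmark(seed=1)   # ~1 minute on one CPU
print(f"train top-1        {res['train_top1']:.3f}")
print(f"test  top-1        {res['test_top1']:.3f}")
print(f"anomaly AP         {res['anomaly_ap']:.3f}")
print(f"flagged / planted  {res['num_flagged']} / {res['n_anomalies']}")
print(f"behavior clusters  {res['num_clusters']}")
```

prints

```
train top-1        1.000
test  top-1        1.000
anomaly AP         1.000
flagged / planted  5 / 5
behavior clusters  4
```

i.e. the encoder, trained on 200 normal clips (50 per class, 50 frames
each), classifies the 40 held-out normal clips perfectly; the detector
recovers all four behavior clusters and flags exactly the five planted
anomalies, giving an average precision of 1.0 on this synthetic
benchmark. The same pipeline is available from the shell:

```bash
abnet simulate --out run/ --clips-per-class 50 --seed 1
abnet train    --data run/train.npz --out run/model.npz --seed 1
abnet encode   --data run/test.npz  --model run/model.npz --out run/emb.npz
abnet detect   --embeddings run/emb.npz --out run/report.json
abnet eval     --report run/report.json --truth run/truth.txt \
               --embeddings run/emb.npz --model run/model.npz \
               --out run/metrics.json
```

For sklearn-style composition, `abnet.STGCNClassifier`
(fit/predict/transform — `transform` returns embeddings) and
`abnet.BehaviorAnomalyDetector` (fit/predict/score_samples, outlier
convention −1 = abnormal) wrap the library.

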