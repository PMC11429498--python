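"""Enhanced spatio-temporal graph-convolutional encoder.

Architecture, per block::

    x ──> spatial graph conv (per-partition joint mixing + 1x1 channel mix)
       ──> batch norm ──> ReLU
       ──> squeeze-and-excitation channel gate          (optional)
       ──> temporal stage: multi-branch TCN  or  kernel-9 temporal conv
       ──> batch norm ──> (+ residual) ──> ReLU

The spatial convolution follows ``y = Ω_{1×1}( X · ((Â_k + G) ⊙ M_k) )``
summed over partitions, where ``Â_k`` is the symmetric-normalized
adjacency partition, ``M_k`` a learnable edge-importance mask
(all-ones at init) and ``G = Λ·φ`` the Gaussian noise perturbation,
resampled per forward pass during training and disabled in eval.  With
noise off, SE off and the single kernel-9 temporal convolution, the
block reduces exactly to the original ST-GCN block.

A full model is an input batch norm, a stack of blocks, global average
pooling over (time, joints, animals) to a fixed-length behavior
embedding, and a linear softmax classifier head.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autograd import Tensor, concat, einsum2, maxpool_time, parameter
from .graph import NoiseConfig, SkeletonGraph, partition_adjacency, sample_noise_matrix

__all__ = [
    "ModelConfig",
    "STGCN",
    "spatial_graph_conv",
    "se_squeeze",
    "se_recalibrate",
    "mtcn",
    "stgcn_block",
    "classify",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Structural hyperparameters of the encoder.

    ``channels[i]`` is the output width of block ``i``; ``strides[i]`` its
    temporal stride (2 halves the time axis).  The default plan follows
    the original ST-GCN convention: nine blocks, three per width, stride 2
    at each width change.  Toggles switch each enhancement on or off; with
    all three off the model is the vanilla ST-GCN baseline.
    """

    channels: tuple[int, ...] = (64, 64, 64, 128, 128, 128, 256, 256, 256)
    strides: tuple[int, ...] = (1, 1, 1, 2, 1, 1, 2, 1, 1)
    num_classes: int = 4
    in_channels: int = 3
    partition_strategy: str = "distance"
    se_reduction: int = 4
    temporal_kernel: int = 9  # baseline single-branch kernel
    noise_on: bool = True
    se_on: bool = True
    mtcn_on: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    dtype: str = "float32"  # compute precision; float64 for gradient checks

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if self.mtcn_on:
            for c in self.channels:
                if c % 6 != 0:
                    raise ValueError(
                        f"MTCN splits channels into 6 equal branches; width {c} "
                        "is not divisible by 6"
                    )

    @property
    def embedding_dim(self) -> int:
        return self.channels[-1]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["noise"] = NoiseConfig(**d.get("noise", {}))
        d["channels"] = tuple(d["channels"])
        d["strides"] = tuple(d["strides"])
        return cls(**d)


# ---------------------------------------------------------------------------
# functional pieces (the layer math, usable standalone)
# ---------------------------------------------------------------------------

def spatial_graph_conv(
    x: Tensor,
    partitions: list[np.ndarray],
    weights: list[Tensor],
    masks: list[Tensor],
    noise: np.ndarray | None = None,
) -> Tensor:
    """Per-partition joint mixing followed by 1×1 channel mixing, summed.

    ``x`` is (N, C_in, T, V).  For each partition k the joint-mixing
    matrix is ``(Â_k + G) ⊙ M_k`` (G omitted when ``noise`` is None), and
    the 1×1 convolution is a channel matrix ``weights[k]`` of shape
    (C_out, C_in).
    """
    if x.value.shape[3] != partitions[0].shape[0]:
        raise ValueError(
            f"joint axis {x.value.shape[3]} does not match graph with "
            f"{partitions[0].shape[0]} joints"
        )
    out = None
    for Ak, W, M in zip(partitions, weights, masks):
        mix = Tensor(Ak) + Tensor(noise) if noise is not None else Tensor(Ak)
        mix = mix * M  # learnable edge-importance mask, elementwise
        agg = einsum2("nctv,vw->nctw", x, mix)
        y = einsum2("oc,nctv->notv", W, agg)
        out = y if out is None else out + y
    return out


def se_squeeze(u: Tensor) -> Tensor:
    """Global average over time × joints: (N, C, T, V) -> (N, C)."""
    return u.mean(axis=(2, 3))


def se_recalibrate(u: Tensor, w_reduce: Tensor, w_expand: Tensor) -> Tensor:
    """Squeeze-and-excitation channel gate.

    ``s = sigmoid(W2 · ReLU(W1 · z))`` with ``z`` the per-channel global
    mean; the feature map is rescaled channel-wise by ``s ∈ (0,1)``.
    ``W1`` is (C/r, C), ``W2`` is (C, C/r).
    """
    z = se_squeeze(u)  # (N, C)
    h = einsum2("rc,nc->nr", w_reduce, z).relu()
    s = einsum2("cr,nr->nc", w_expand, h).sigmoid()
    N, C = s.value.shape
    return u * s.reshape(N, C, 1, 1)


def temporal_conv(
    x: Tensor, weight: Tensor, kernel: int, dilation: int = 1, stride: int = 1
) -> Tensor:
    """1-D convolution along time with same padding.

    ``weight`` has shape (C_out, C_in, kernel).  Output length is
    ``ceil(T / stride)``.
    """
    T = x.value.shape[2]
    out_len = -(-T // stride)
    pad_total = (kernel - 1) * dilation
    left = pad_total // 2
    xp = x.pad_time(left, pad_total - left)
    out = None
    for t in range(kernel):
        sl = xp.slice_time(t * dilation, t * dilation + (out_len - 1) * stride + 1, stride)
        y = einsum2("oc,nctv->notv", _tap(weight, t), sl)
        out = y if out is None else out + y
    return out


def _tap(weight: Tensor, t: int) -> Tensor:
    """Select kernel tap ``t``: (C_out, C_in, K) -> (C_out, C_in)."""
    k = weight.value.shape[2]

    def vjp(g):
        out = np.zeros_like(weight.value)
        out[:, :, t] = g
        return out

    return Tensor(weight.value[:, :, t], parents=(weight,), vjps=(vjp,))


def conv1x1(x: Tensor, weight: Tensor, stride: int = 1) -> Tensor:
    """Pointwise channel mixing, optionally strided along time."""
    y = einsum2("oc,nctv->notv", weight, x)
    if stride > 1:
        y = y.slice_time(0, y.value.shape[2], stride)
    return y


def mtcn(
    x: Tensor,
    entry: Tensor,
    branch_conv1x1: Tensor,
    branch_dilated: list[Tensor],
    exit_w: Tensor,
    stride: int = 1,
) -> Tensor:
    """Multi-branch temporal convolution.

    An entry 1×1 conv maps to a working width divisible by 6, which is
    split into six equal groups processed by parallel branches: a 1×1
    conv, a window-3 temporal max pool, and four kernel-3 temporal convs
    at dilations 1–4.  Branch outputs are concatenated channel-wise and
    remixed by an exit 1×1 conv.  Same padding: time length is preserved
    at stride 1 and halved (ceil) at stride 2.
    """
    h = conv1x1(x, entry)
    c_mid = h.value.shape[1]
    if c_mid % 6 != 0:
        raise ValueError(f"MTCN working width {c_mid} not divisible by 6")
    w = c_mid // 6
    groups = [_channel_slice(h, i * w, (i + 1) * w) for i in range(6)]
    outs = [
        conv1x1(groups[0], branch_conv1x1, stride=stride),
        maxpool_time(groups[1], window=3, stride=stride),
    ]
    for i, (d, wt) in enumerate(zip((1, 2, 3, 4), branch_dilated)):
        outs.append(temporal_conv(groups[2 + i], wt, kernel=3, dilation=d, stride=stride))
    cat = concat(outs, axis=1)
    return conv1x1(cat, exit_w)


def _channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    shape = x.value.shape

    def vjp(g):
        out = np.zeros(shape, dtype=g.dtype)
        out[:, start:stop] = g
        return out

    return Tensor(x.value[:, start:stop], parents=(x,), vjps=(vjp,))


def classify(embedding: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from pooled embeddings (pure NumPy)."""
    logits = embedding @ weight.T + bias
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# layers with parameters and state
# ---------------------------------------------------------------------------

class BatchNorm:
    """Batch normalization over (N, T, V) per channel with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = parameter(np.ones(c))
        self.beta = parameter(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        C = x.value.shape[1]
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.value.ravel()
            )
            n = x.value.shape[0] * x.value.shape[2] * x.value.shape[3]
            unbiased = var.value.ravel() * (n / max(n - 1, 1))
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
            inv = (var + self.eps).pow_const(-0.5)
            xhat = xc * inv
        else:
            dt = x.value.dtype
            mu = self.running_mean.reshape(1, C, 1, 1).astype(dt)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(dt)
            xhat = (x - Tensor(mu)) * Tensor(inv.reshape(1, C, 1, 1))
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


def _init_weight(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
    return rng.normal(0.0, bound, size=shape)


class SEGate:
    def __init__(self, c: int, r: int, rng: np.random.Generator):
        if c % r != 0:
            raise ValueError(f"SE reduction ratio {r} does not divide channel width {c}")
        self.w_reduce = parameter(_init_weight(rng, c, (c // r, c)))
        self.w_expand = parameter(_init_weight(rng, c // r, (c, c // r)))

    def parameters(self):
        return [self.w_reduce, self.w_expand]

    def __call__(self, u: Tensor) -> Tensor:
        return se_recalibrate(u, self.w_reduce, self.w_expand)


class GraphConvLayer:
    def __init__(self, c_in: int, c_out: int, n_parts: int, rng: np.random.Generator, k: int):
        self.weights = [
            parameter(_init_weight(rng, c_in * n_parts, (c_out, c_in)))
            for _ in range(n_parts)
        ]
        self.masks = [parameter(np.ones((k, k))) for _ in range(n_parts)]

    def parameters(self):
        return self.weights + self.masks

    def __call__(self, x: Tensor, partitions, noise) -> Tensor:
        return spatial_graph_conv(x, partitions, self.weights, self.masks, noise)


class MTCNLayer:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        if c_out % 6 != 0:
            raise ValueError(f"MTCN channel width {c_out} not divisible by 6")
        w = c_out // 6
        self.entry = parameter(_init_weight(rng, c_in, (c_out, c_in)))
        self.branch_conv1x1 = parameter(_init_weight(rng, w, (w, w)))
        self.branch_dilated = [
            parameter(_init_weight(rng, w * 3, (w, w, 3))) for _ in range(4)
        ]
        self.exit_w = parameter(_init_weight(rng, c_out, (c_out, c_out)))

    def parameters(self):
        return [self.entry, self.branch_conv1x1, *self.branch_dilated, self.exit_w]

    def __call__(self, x: Tensor, stride: int) -> Tensor:
        return mtcn(x, self.entry, self.branch_conv1x1, self.branch_dilated, self.exit_w, stride)


class TemporalConvLayer:
    """Single-branch kernel-9 temporal convolution (baseline stage)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.weight = parameter(_init_weight(rng, c_in * kernel, (c_out, c_in, kernel)))

    def parameters(self):
        return [self.weight]

    def __call__(self, x: Tensor, stride: int) -> Tensor:
        return temporal_conv(x, self.weight, kernel=self.kernel, stride=stride)


class STGCNBlock:
    """One enhanced spatio-temporal block (see module docstring)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        stride: int,
        cfg: ModelConfig,
        graph: SkeletonGraph,
        rng: np.random.Generator,
    ):
        n_parts = len(graph.partitions)
        self.cfg = cfg
        self.stride = stride
        self.gcn = GraphConvLayer(c_in, c_out, n_parts, rng, graph.k)
        self.bn1 = BatchNorm(c_out)
        self.se = SEGate(c_out, cfg.se_reduction, rng) if cfg.se_on else None
        if cfg.mtcn_on:
            self.temporal = MTCNLayer(c_out, c_out, rng)
        else:
            self.temporal = TemporalConvLayer(c_out, c_out, cfg.temporal_kernel, rng)
        self.bn2 = BatchNorm(c_out)
        if c_in == c_out and stride == 1:
            self.res_conv = None
            self.res_bn = None
        else:
            self.res_conv = parameter(_init_weight(rng, c_in, (c_out, c_in)))
            self.res_bn = BatchNorm(c_out)

    def parameters(self):
        ps = self.gcn.parameters() + self.bn1.parameters() + self.bn2.parameters()
        if self.se is not None:
            ps += self.se.parameters()
        ps += self.temporal.parameters()
        if self.res_conv is not None:
            ps += [self.res_conv] + self.res_bn.parameters()
        return ps

    def __call__(
        self,
        x: Tensor,
        partitions,
        noise: np.ndarray | None,
        training: bool,
    ) -> Tensor:
        h = self.gcn(x, partitions, noise)
        h = self.bn1(h, training).relu()
        if self.se is not None:
            h = self.se(h)
        h = self.temporal(h, self.stride)
        h = self.bn2(h, training)
        if self.res_conv is None:
            res = x
        else:
            res = conv1x1(x, self.res_conv, stride=self.stride)
            res = self.res_bn(res, training)
        return (h + res).relu()


def stgcn_block(block: STGCNBlock, x: Tensor, partitions, noise=None, training=False) -> Tensor:
    """Functional entry point for a single block forward pass."""
    return block(x, partitions, noise, training)


class STGCN:
    """Encoder + classifier: block stack, global pooling, softmax head."""

    def __init__(self, cfg: ModelConfig, graph: SkeletonGraph, seed: int = 0):
        if not graph.partitions:
            partition_adjacency(graph, cfg.partition_strategy)
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.graph = graph
        self.input_bn = BatchNorm(cfg.in_channels)
        self.blocks: list[STGCNBlock] = []
        c_prev = cfg.in_channels
        for c_out, stride in zip(cfg.channels, cfg.strides):
            self.blocks.append(STGCNBlock(c_prev, c_out, stride, cfg, graph, rng))
            c_prev = c_out
        self.head_w = parameter(_init_weight(rng, c_prev, (cfg.num_classes, c_prev)))
        self.head_b = parameter(np.zeros(cfg.num_classes))
        self.training = True
        dt = np.dtype(cfg.dtype)
        for p in self.parameters():
            p.value = p.value.astype(dt)
        self._partitions = [a.astype(dt) for a in graph.partitions]

    # -- mode ----------------------------------------------------------
    def train_mode(self) -> "STGCN":
        self.training = True
        return self

    def eval_mode(self) -> "STGCN":
        self.training = False
        return self

    def parameters(self):
        ps = self.input_bn.parameters()
        for b in self.blocks:
            ps += b.parameters()
        ps += [self.head_w, self.head_b]
        return ps

    # -- forward -------------------------------------------------------
    def _prepare(self, batch: np.ndarray) -> Tensor:
        """(N, C, T, V, M) array -> (N*M, C, T, V) graph input."""
        arr = np.asarray(batch, dtype=self.cfg.dtype)
        if arr.ndim != 5:
            raise ValueError("expected rank-5 input (N, C, T, V, M)")
        if arr.shape[3] != self.graph.k:
            raise ValueError(
                f"input has {arr.shape[3]} joints but the graph has {self.graph.k}"
            )
        N, C, T, V, M = arr.shape
        x = np.moveaxis(arr, 4, 1).reshape(N * M, C, T, V)
        return Tensor(x)

    def _noise(self, rng: np.random.Generator | None) -> np.ndarray | None:
        cfg = self.cfg
        if not cfg.noise_on:
            return None
        if not self.training and not cfg.noise.enabled_in_eval:
            return None
        if rng is None:
            rng = np.random.default_rng(0)
        return sample_noise_matrix(self.graph, cfg.noise, rng).astype(self.cfg.dtype)

    def forward_embedding(self, batch: np.ndarray, rng=None) -> Tensor:
        """Pooled behavior embedding per clip, as a graph Tensor."""
        x = self._prepare(batch)
        x = self.input_bn(x, self.training)
        noise = self._noise(rng)
        for block in self.blocks:
            x = block(x, self._partitions, noise, self.training)
        # global average pool over time and joints, then over animals (M=1)
        return x.mean(axis=(2, 3))

    def forward_logits(self, batch: np.ndarray, rng=None) -> Tensor:
        emb = self.forward_embedding(batch, rng)
        return einsum2("oc,nc->no", self.head_w, emb) + self.head_b.reshape(1, -1)

    # -- inference-facing API -------------------------------------------
    def encode(self, batch: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Deterministic per-clip embeddings in eval mode."""
        was_training = self.training
        self.eval_mode()
        outs = []
        for i in range(0, len(batch), batch_size):
            outs.append(self.forward_embedding(batch[i : i + batch_size]).value)
        self.training = was_training
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, self.cfg.embedding_dim))

    def predict_proba(self, batch: np.ndarray, batch_size: int = 64) -> np.ndarray:
        emb = self.encode(batch, batch_size)
        return classify(emb, self.head_w.value, self.head_b.value)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: STGCN, path) -> None:
    """Single-file archive of named parameter tensors + model config."""
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i:04d}"] = p.value
    bns = _all_batchnorms(model)
    for i, bn in enumerate(bns):
        arrays[f"bn_{i:04d}_mean"] = bn.running_mean
        arrays[f"bn_{i:04d}_var"] = bn.running_var
    cfg_json = json.dumps(
        {"model": model.cfg.to_dict(), "graph": {
            "num_joints": model.graph.k,
            "edges": [list(e) for e in model.graph.edges],
            "joint_names": list(model.graph.joint_names),
        }},
        sort_keys=True,
    )
    arrays["config"] = np.frombuffer(cfg_json.encode("utf-8"), dtype=np.uint8)
    buf = _stdio.BytesIO()
    np.savez(buf, **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path) -> STGCN:
    from .graph import build_skeleton_graph

    with np.load(path) as npz:
        cfg_json = json.loads(bytes(npz["config"].tobytes()).decode("utf-8"))
        cfg = ModelConfig.from_dict(cfg_json["model"])
        gspec = cfg_json["graph"]
        graph = build_skeleton_graph(
            gspec["num_joints"],
            [tuple(e) for e in gspec["edges"]],
            joint_names=tuple(gspec["joint_names"]),
        )
        model = STGCN(cfg, graph, seed=0)
        for i, p in enumerate(model.parameters()):
            p.value = npz[f"param_{i:04d}"]
        for i, bn in enumerate(_all_batchnorms(model)):
            bn.running_mean = npz[f"bn_{i:04d}_mean"]
            bn.running_var = npz[f"bn_{i:04d}_var"]
    return model.eval_mode()


def _all_batchnorms(model: STGCN) -> list[BatchNorm]:
    bns = [model.input_bn]
    for b in model.blocks:
        bns += [b.bn1, b.bn2]
        if b.res_bn is not None:
            bns.append(b.res_bn)
    return bns
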