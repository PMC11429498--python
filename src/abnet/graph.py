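"""Skeleton joint graph: adjacency, normalization, partitions, noise.

The joint graph drives the spatial half of the spatio-temporal graph
convolution.  ``A`` is the binary adjacency with self-loops, ``Lambda``
its diagonal degree matrix, and the network convolves over the symmetric
normalization ``Λ^{-1/2} A Λ^{-1/2}`` — either as a single matrix
(``uniform`` partitioning) or split into a self-loop part and a neighbor
part (``distance`` partitioning) that are convolved with separate
weights and summed.

The Gaussian noise matrix ``G = Λ·φ`` with ``φ ~ N(μ, σ²)`` is a
training-time perturbation added to the spatially aggregated features; it
creates transient links between non-adjacent joints so the encoder is not
locked to the hand-drawn skeleton topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MOUSE_KEYPOINTS

__all__ = [
    "SkeletonGraph",
    "NoiseConfig",
    "MOUSE_EDGES",
    "build_skeleton_graph",
    "build_mouse_graph",
    "normalize_adjacency",
    "partition_adjacency",
    "sample_noise_matrix",
]

#: Anatomical tree over the 12-joint mouse skeleton (11 edges, by name).
MOUSE_EDGES: tuple[tuple[str, str], ...] = (
    ("nose", "head"),
    ("head", "L_ear"),
    ("head", "R_ear"),
    ("head", "neck"),
    ("neck", "L_forepaw"),
    ("neck", "R_forepaw"),
    ("neck", "spine_mid"),
    ("spine_mid", "L_hindpaw"),
    ("spine_mid", "R_hindpaw"),
    ("spine_mid", "tail_base"),
    ("tail_base", "tail_tip"),
)


@dataclass
class NoiseConfig:
    """Parameters of the adjacency perturbation ``G = Λ·φ``, ``φ~N(μ, σ²)``.

    ``sigma`` is the standard deviation of the noise entries; ``sigma=0``
    degenerates to the deterministic matrix ``μ·Λ``.  By default noise is
    resampled on every training forward pass and disabled at inference.
    """

    mu: float = 0.0
    sigma: float = 0.05
    resample_mode: str = "per_forward"  # or "fixed"
    enabled_in_eval: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.resample_mode not in ("per_forward", "fixed"):
            raise ValueError(f"unknown resample_mode: {self.resample_mode!r}")


@dataclass
class SkeletonGraph:
    """Joint graph with adjacency, degree normalizer and partition stack."""

    num_joints: int
    edges: list[tuple[int, int]]
    A: np.ndarray = field(default=None)  # type: ignore[assignment]
    Lambda: np.ndarray = field(default=None)  # type: ignore[assignment]
    partitions: list[np.ndarray] = field(default_factory=list)
    strategy: str = ""
    joint_names: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return self.num_joints


def build_skeleton_graph(
    k: int,
    edges,
    joint_names: tuple[str, ...] = (),
) -> SkeletonGraph:
    """Build the joint graph with self-loops: ``A = I + symmetric edges``.

    Duplicate edges are accepted (idempotent); self-pairs and out-of-range
    indices are rejected.  Partitions stay empty until
    :func:`partition_adjacency` is called.
    """
    A = np.eye(k, dtype=np.float64)
    for i, j in edges:
        i, j = int(i), int(j)
        if not (0 <= i < k and 0 <= j < k):
            raise ValueError(f"edge ({i},{j}) out of range for k={k}")
        if i == j:
            raise ValueError(f"self-pair edge ({i},{i}) not allowed")
        A[i, j] = 1.0
        A[j, i] = 1.0
    Lambda = np.diag(A.sum(axis=1))
    return SkeletonGraph(
        num_joints=k,
        edges=[(min(i, j), max(i, j)) for i, j in edges],
        A=A,
        Lambda=Lambda,
        joint_names=joint_names,
    )


def build_mouse_graph() -> SkeletonGraph:
    """Default 12-joint mouse graph with the anatomical edge tree."""
    name_to_idx = {n: i for i, n in enumerate(MOUSE_KEYPOINTS)}
    edges = [(name_to_idx[a], name_to_idx[b]) for a, b in MOUSE_EDGES]
    return build_skeleton_graph(len(MOUSE_KEYPOINTS), edges, joint_names=MOUSE_KEYPOINTS)


def normalize_adjacency(g: SkeletonGraph, A: np.ndarray | None = None) -> np.ndarray:
    """Symmetric normalization ``Λ^{-1/2} A Λ^{-1/2}``.

    ``Λ`` is always the degree matrix of the *full* adjacency (with
    self-loops), also when only a partition of ``A`` is being normalized —
    this keeps the partition stack summing to the full normalized matrix.
    """
    target = g.A if A is None else A
    deg = np.diag(g.Lambda).copy()
    if np.any(deg <= 0):
        raise ValueError("degenerate graph: joint with zero degree")
    d = 1.0 / np.sqrt(deg)
    return d[:, None] * target * d[None, :]


def partition_adjacency(g: SkeletonGraph, strategy: str = "distance") -> list[np.ndarray]:
    """Split the normalized adjacency into the partition stack ``A_k``.

    ``uniform``
        one matrix, the full normalized adjacency.
    ``distance``
        two matrices by hop distance: the self-loop (distance-0) part and
        the neighbor (distance-1) part, normalized consistently so they
        sum elementwise to the uniform matrix.

    The result is stored on the graph and returned.
    """
    if strategy == "uniform":
        parts = [normalize_adjacency(g)]
    elif strategy == "distance":
        self_part = np.eye(g.k)
        neigh_part = g.A - self_part
        parts = [normalize_adjacency(g, self_part), normalize_adjacency(g, neigh_part)]
    else:
        raise ValueError(f"unknown partition strategy: {strategy!r}")
    g.partitions = parts
    g.strategy = strategy
    return parts


def sample_noise_matrix(
    g: SkeletonGraph, cfg: NoiseConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw the ``k×k`` noise matrix ``G = Λ·φ`` with ``φ_ij ~ N(μ, σ²)``.

    Row ``i`` of ``G`` is scaled by the degree ``Λ_ii``, so entries in row
    ``i`` have standard deviation ``Λ_ii·σ``.  ``σ=0`` gives exactly
    ``μ·Λ_row`` (deterministic).  The same generator state yields the same
    matrix.
    """
    k = g.k
    if cfg.sigma == 0.0:
        phi = np.full((k, k), cfg.mu)
    else:
        phi = rng.normal(cfg.mu, cfg.sigma, size=(k, k))
    return g.Lambda @ phi


# ---------------------------------------------------------------------------
# structured-text graph configuration
# ---------------------------------------------------------------------------

def save_graph_config(
    g: SkeletonGraph, path, noise: NoiseConfig | None = None
) -> None:
    """Write joint names, edges, partition strategy and noise to YAML."""
    import yaml

    names = list(g.joint_names) if g.joint_names else [
        f"joint_{i}" for i in range(g.k)
    ]
    payload = {
        "joints": names,
        "edges": [[names[i], names[j]] for i, j in g.edges],
        "partition_strategy": g.strategy or "distance",
    }
    if noise is not None:
        payload["noise"] = {"mu": noise.mu, "sigma": noise.sigma}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_graph_config(path) -> tuple[SkeletonGraph, NoiseConfig]:
    """Read a YAML graph config; returns the built graph (partitioned) and noise."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    names = list(payload["joints"])
    idx = {n: i for i, n in enumerate(names)}
    edges = [(idx[a], idx[b]) for a, b in payload.get("edges", [])]
    g = build_skeleton_graph(len(names), edges, joint_names=tuple(names))
    partition_adjacency(g, payload.get("partition_strategy", "distance"))
    noise = NoiseConfig(**payload.get("noise", {}))
    return g, noise
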