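"""Semi-supervised abnormal-behavior detection on pooled embeddings.

The detector never sees abnormal samples during training.  Clip
embeddings from the encoder are reduced with PCA, clustered with DBSCAN,
and every clip that joins no density cluster is flagged abnormal: the
clusters are the learned normal behaviors, the noise set is the anomaly
set.

DBSCAN is implemented here rather than wrapped because the package fixes
a deterministic border-point rule (a border point joins the cluster of
its lowest-index core neighbor) so cluster membership is independent of
input order; the standard library implementations leave that tie
order-dependent.  Correctness is cross-checked in the test suite against
both a brute-force density-reachability closure and scikit-learn.

A continuous anomaly score — the distance to the ``min_samples``-th
nearest neighbor (self included) in reduced space — accompanies the
binary flag so a precision–recall curve and average precision can be
computed; a point is a DBSCAN core point exactly when its score is
``<= eps``, making the flag the natural operating point of the score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

__all__ = [
    "PCAReduction",
    "AnomalyReport",
    "PrMetrics",
    "pca_fit_reduce",
    "dbscan_cluster",
    "knn_scores",
    "estimate_eps",
    "detect_abnormal",
    "average_precision",
]


@dataclass
class PCAReduction:
    """Fitted mean-centered orthogonal projection and reduced points.

    When ``scale`` is set (whitened reduction), projected coordinates are
    divided per-component by the standard deviation along that component,
    so every retained direction has unit variance on the fit data.
    """

    points: np.ndarray  # (n, n_components)
    components: np.ndarray  # (n_components, dim)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    scale: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        pts = (np.asarray(X) - self.mean) @ self.components.T
        if self.scale is not None:
            pts = pts / self.scale
        return pts


@dataclass
class AnomalyReport:
    """Per-clip cluster assignment, anomaly score and flag."""

    cluster_ids: np.ndarray  # -1 = no cluster
    scores: np.ndarray  # k-NN distance in reduced space, >= 0
    is_abnormal: np.ndarray  # bool, == (cluster_ids == -1)
    num_clusters: int
    eps: float
    min_samples: int
    pca_dims: int
    reduced: np.ndarray | None = None

    @property
    def num_abnormal(self) -> int:
        return int(self.is_abnormal.sum())

    @property
    def num_normal(self) -> int:
        return int((~self.is_abnormal).sum())

    def to_json(self, path=None) -> str:
        payload = {
            "params": {
                "eps": self.eps,
                "min_samples": self.min_samples,
                "pca_dims": self.pca_dims,
                "num_clusters": self.num_clusters,
            },
            "clips": [
                {
                    "clip": int(i),
                    "cluster_id": int(c),
                    "score": float(s),
                    "is_abnormal": bool(a),
                }
                for i, (c, s, a) in enumerate(
                    zip(self.cluster_ids, self.scores, self.is_abnormal)
                )
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PrMetrics:
    """Precision–recall curve, operating-point counts, and AP."""

    precision: np.ndarray
    recall: np.ndarray
    ap: float
    tp: int = 0
    fp: int = 0
    fn: int = 0


def pca_fit_reduce(
    embeddings: np.ndarray, n_components: int, whiten: bool = False
) -> PCAReduction:
    """Mean-centered orthogonal projection onto the top principal axes.

    Components are ordered by explained variance; the sign of each
    component is fixed so its largest-magnitude loading is positive,
    making the projection deterministic.  With ``whiten`` the projected
    coordinates are rescaled to unit variance per component, which puts
    the retained directions on a common scale — a prerequisite for
    density clustering with a single global radius.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 embedding vectors")
    if not (1 <= n_components <= min(X.shape)):
        raise ValueError(
            f"n_components={n_components} must be in [1, {min(X.shape)}]"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scale = None
    pts = (X - pca.mean_) @ comps.T
    if whiten:
        scale = np.sqrt(np.maximum(pca.explained_variance_, 1e-24))
        pts = pts / scale
    return PCAReduction(
        points=pts,
        components=comps,
        mean=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scale=scale,
    )


def dbscan_cluster(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Density clustering; returns labels with -1 for noise.

    A core point has at least ``min_samples`` points (itself included)
    within Euclidean distance ``eps``.  Clusters are the connected
    components of the core-point graph; border points (non-core within
    ``eps`` of a core) join the cluster of their lowest-index core
    neighbor.  Cluster ids are numbered by first point index, so the
    labeling is a pure function of the point set.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if n == 0:
        return np.zeros(0, dtype=int)
    D = cdist(X, X)
    within = D <= eps
    core = within.sum(axis=1) >= min_samples
    labels = np.full(n, -1, dtype=int)
    # connected components over core points
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(within[p] & core):
                if labels[q] == -1:
                    labels[q] = cluster
                    stack.append(q)
        cluster += 1
    # border points: lowest-index core neighbor decides
    for i in range(n):
        if core[i] or not within[i][core].any():
            continue
        neighbor_cores = np.flatnonzero(within[i] & core)
        labels[i] = labels[neighbor_cores[0]]
    return labels


def knn_scores(points: np.ndarray, k: int, reference: np.ndarray | None = None) -> np.ndarray:
    """Distance to the k-th nearest neighbor (self counts when reference is the set itself)."""
    X = np.asarray(points, dtype=float)
    R = X if reference is None else np.asarray(reference, dtype=float)
    D = np.sort(cdist(X, R), axis=1)
    k = min(k, D.shape[1])
    return D[:, k - 1]


def estimate_eps(points: np.ndarray, min_samples: int, factor: float = 2.5) -> float:
    """k-distance heuristic: median min_samples-NN distance × factor."""
    scores = knn_scores(points, min_samples)
    med = float(np.median(scores))
    if med == 0.0:
        # degenerate (duplicated points); any positive radius works
        return max(float(scores.max()) * factor, 1e-12)
    return med * factor


def detect_abnormal(
    embeddings: np.ndarray,
    pca_dims: int = 4,
    eps: float | None = None,
    min_samples: int = 5,
    whiten: bool = True,
    eps_factor: float = 2.5,
    keep_reduced: bool = True,
) -> AnomalyReport:
    """Full pipeline: whitened PCA reduction → DBSCAN → flags + k-NN scores.

    When ``eps`` is not given it is set by the k-distance heuristic
    (median of the ``min_samples``-NN distances × ``eps_factor``).
    """
    X = np.asarray(embeddings, dtype=float)
    if X.shape[0] < min_samples:
        raise ValueError("need at least min_samples embeddings")
    pca_dims = min(pca_dims, min(X.shape))
    red = pca_fit_reduce(X, pca_dims, whiten=whiten)
    pts = red.points
    if eps is None:
        eps = estimate_eps(pts, min_samples, eps_factor)
    labels = dbscan_cluster(pts, eps, min_samples)
    scores = knn_scores(pts, min_samples)
    return AnomalyReport(
        cluster_ids=labels,
        scores=scores,
        is_abnormal=labels == -1,
        num_clusters=int(labels.max()) + 1 if (labels >= 0).any() else 0,
        eps=float(eps),
        min_samples=min_samples,
        pca_dims=pca_dims,
        reduced=pts if keep_reduced else None,
    )


def average_precision(scores: np.ndarray, truth: np.ndarray) -> PrMetrics:
    """Area under the precision–recall curve by step-wise summation.

    Samples are ranked by descending score (higher = more anomalous);
    tied scores are processed as a single threshold.  AP is the sum of
    precision × recall-increment over thresholds — the step integral
    ``∫ p(r) dr``.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    n_pos = int(truth.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    precisions, recalls = [], []
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # tie group = one threshold
            j += 1
        tp += int(t[i:j].sum())
        fp += (j - i) - int(t[i:j].sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        precisions.append(precision)
        recalls.append(recall)
        ap += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    fn = n_pos - tp if tp < n_pos else 0
    return PrMetrics(
        precision=np.array(precisions),
        recall=np.array(recalls),
        ap=float(ap),
        tp=tp,
        fp=fp,
        fn=fn,
    )


def plot_clusters(report: AnomalyReport, path, truth: np.ndarray | None = None) -> None:
    """2-D scatter of the first two reduced dimensions, anomalies in black."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = report.reduced
    if pts is None or pts.shape[1] < 2:
        raise ValueError("report carries no 2-D reduced coordinates")
    fig, ax = plt.subplots(figsize=(6, 5))
    normal = ~report.is_abnormal
    ax.scatter(
        pts[normal, 0], pts[normal, 1], c=report.cluster_ids[normal],
        cmap="tab10", s=18, label="clustered (normal)",
    )
    ax.scatter(
        pts[report.is_abnormal, 0], pts[report.is_abnormal, 1],
        c="black", s=30, marker="o", label="no cluster (abnormal)",
    )
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
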