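"""scikit-learn style estimators over the encoder and the anomaly pipeline.

``STGCNClassifier`` is a classifier (fit / predict / predict_proba /
transform) over rank-5 skeleton tensors; ``transform`` returns the pooled
behavior embeddings, so the classifier doubles as the feature extractor
feeding ``BehaviorAnomalyDetector``, which follows the outlier-detector
convention (fit on normal data; ``predict`` returns +1 normal / -1
abnormal; ``score_samples`` returns the continuous anomaly score, larger
meaning more anomalous).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, OutlierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .anomaly import AnomalyReport, dbscan_cluster, estimate_eps, knn_scores, pca_fit_reduce
from .graph import NoiseConfig, build_mouse_graph, build_skeleton_graph
from .io import ClipDataset
from .network import STGCN, ModelConfig
from .training import TrainConfig, topk_accuracy, train

__all__ = ["STGCNClassifier", "BehaviorAnomalyDetector"]


def _as_tensor(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 4:  # (N, C, T, V) -> single animal
        arr = arr[..., None]
    if arr.ndim != 5:
        raise ValueError("X must be a rank-5 skeleton tensor (N, C, T, V, M)")
    return arr


class STGCNClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Behavior classifier built on the enhanced spatio-temporal encoder.

    Parameters mirror the model and training configuration; all three
    enhancement toggles (adjacency noise, SE channel attention,
    multi-branch temporal convolution) can be switched off to recover the
    vanilla ST-GCN baseline.

    Attributes (after ``fit``)
    --------------------------
    model_ : the fitted encoder + softmax head
    history_ : per-epoch loss and accuracy record
    classes_ : sorted unique class labels
    """

    def __init__(
        self,
        channels=(16, 16, 32),
        strides=(1, 1, 2),
        noise_on=True,
        se_on=True,
        mtcn_on=False,
        se_reduction=4,
        noise_mu=0.0,
        noise_sigma=0.05,
        learning_rate=0.1,
        batch_size=64,
        epochs=100,
        momentum=0.9,
        weight_decay=1e-4,
        lr_decay_epochs=(40, 80),
        lr_decay_factor=0.1,
        augment_on=True,
        edges=None,
        num_joints=12,
        frame_size=(640.0, 480.0),
        coords_normalized=True,
        egocentric=True,
        seed=0,
    ):
        self.channels = channels
        self.strides = strides
        self.noise_on = noise_on
        self.se_on = se_on
        self.mtcn_on = mtcn_on
        self.se_reduction = se_reduction
        self.noise_mu = noise_mu
        self.noise_sigma = noise_sigma
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_decay_epochs = lr_decay_epochs
        self.lr_decay_factor = lr_decay_factor
        self.augment_on = augment_on
        self.edges = edges
        self.num_joints = num_joints
        self.frame_size = frame_size
        self.coords_normalized = coords_normalized
        self.egocentric = egocentric
        self.seed = seed

    # ------------------------------------------------------------------
    def _build(self, n_classes: int) -> STGCN:
        if self.edges is None and self.num_joints == 12:
            graph = build_mouse_graph()
        else:
            graph = build_skeleton_graph(self.num_joints, self.edges or [])
        cfg = ModelConfig(
            channels=tuple(self.channels),
            strides=tuple(self.strides),
            num_classes=n_classes,
            se_reduction=self.se_reduction,
            noise_on=self.noise_on,
            se_on=self.se_on,
            mtcn_on=self.mtcn_on,
            noise=NoiseConfig(mu=self.noise_mu, sigma=self.noise_sigma),
        )
        return STGCN(cfg, graph, seed=self.seed)

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        if self.egocentric:
            from .io import align_egocentric

            X = align_egocentric(X)
        return X

    def fit(self, X, y, eval_set: ClipDataset | None = None):
        X = self._preprocess(_as_tensor(X))
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.model_ = self._build(len(self.classes_))
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            lr_decay_epochs=tuple(self.lr_decay_epochs),
            lr_decay_factor=self.lr_decay_factor,
            augment_on=self.augment_on,
            seed=self.seed,
        )
        from .io import MOUSE_KEYPOINTS, SkeletonSequence

        # frame metadata keeps the ±px augmentation shifts in pixel units
        # after coordinate normalization
        names = (
            MOUSE_KEYPOINTS
            if X.shape[3] == len(MOUSE_KEYPOINTS)
            else tuple(f"joint_{i}" for i in range(X.shape[3]))
        )
        clips = [
            SkeletonSequence(
                X[i : i + 1],
                keypoint_names=names,
                frame_size=tuple(self.frame_size) if self.frame_size else None,
                normalized=self.coords_normalized,
            )
            for i in range(len(X))
        ]
        ds = ClipDataset(clips=clips, labels=y_enc)
        self.history_ = train(self.model_, ds, eval_set, cfg)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._preprocess(_as_tensor(X)))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Pooled behavior embeddings (eval mode, deterministic)."""
        check_is_fitted(self, "model_")
        return self.model_.encode(self._preprocess(_as_tensor(X)))

    def score(self, X, y) -> float:
        return topk_accuracy(self.predict_proba(X),
                             np.searchsorted(self.classes_, np.asarray(y)), k=1)


class BehaviorAnomalyDetector(OutlierMixin, BaseEstimator):
    """PCA + DBSCAN outlier detector over behavior embeddings.

    Fit on embeddings of (predominantly) normal behavior; ``predict``
    labels each sample +1 (member of a density cluster = normal) or -1
    (no cluster = abnormal).  ``score_samples`` returns the distance to
    the ``min_samples``-th nearest neighbor in reduced space — the
    continuous ranking underlying the flags (score <= eps ⟺ core point).
    """

    def __init__(self, pca_dims=4, eps=None, min_samples=5, eps_factor=2.5, whiten=True):
        self.pca_dims = pca_dims
        self.eps = eps
        self.min_samples = min_samples
        self.eps_factor = eps_factor
        self.whiten = whiten

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.min_samples:
            raise ValueError("need at least min_samples samples")
        dims = min(self.pca_dims, min(X.shape))
        self.reduction_ = pca_fit_reduce(X, dims, whiten=self.whiten)
        pts = self.reduction_.points
        self.eps_ = (
            float(self.eps)
            if self.eps is not None
            else estimate_eps(pts, self.min_samples, self.eps_factor)
        )
        self.labels_ = dbscan_cluster(pts, self.eps_, self.min_samples)
        self.num_clusters_ = int(self.labels_.max()) + 1 if (self.labels_ >= 0).any() else 0
        self.train_points_ = pts
        return self

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "reduction_")
        pts = self.reduction_.transform(np.asarray(X, dtype=float))
        return knn_scores(pts, self.min_samples, reference=self.train_points_)

    def predict(self, X) -> np.ndarray:
        """+1 for normal (joins a cluster), -1 for abnormal."""
        check_is_fitted(self, "reduction_")
        pts = self.reduction_.transform(np.asarray(X, dtype=float))
        joined = np.concatenate([self.train_points_, pts], axis=0)
        labels = dbscan_cluster(joined, self.eps_, self.min_samples)
        new = labels[len(self.train_points_):]
        return np.where(new == -1, -1, 1)

    def fit_report(self, X) -> AnomalyReport:
        """Fit on ``X`` and return the per-clip report for the same set."""
        self.fit(X)
        scores = knn_scores(self.train_points_, self.min_samples)
        return AnomalyReport(
            cluster_ids=self.labels_,
            scores=scores,
            is_abnormal=self.labels_ == -1,
            num_clusters=self.num_clusters_,
            eps=self.eps_,
            min_samples=self.min_samples,
            pca_dims=self.reduction_.points.shape[1],
            reduced=self.train_points_,
        )
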