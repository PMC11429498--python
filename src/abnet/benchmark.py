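"""Reference desk-scale benchmark: the full semi-supervised pipeline.

Generates the standard synthetic study — four normal behavior classes,
50 training clips and 10 held-out clips each, plus five planted
anomalies (two freezing-with-tremor, two erratic-jump, one
limb-dissociation) confined to the test split — trains the enhanced
encoder on the normal clips only, and runs the PCA + DBSCAN detector on
the held-out embeddings.

Model and schedule are scaled to a single CPU: a three-stage encoder of
widths 12/24 (temporal stride 2 at the width change), 100 epochs of SGD
at learning rate 0.1 with one ×0.1 decay at epoch 80, batch size 50.
"""

from __future__ import annotations

import numpy as np

from .anomaly import average_precision, detect_abnormal
from .estimators import STGCNClassifier
from .synthetic import BEHAVIOR_CLASSES, SyntheticDatasetSpec, generate_dataset
from .training import topk_accuracy

__all__ = ["benchmark_data_spec", "run_anomaly_benchmark"]


def benchmark_data_spec(seed: int) -> SyntheticDatasetSpec:
    """50 train + 10 test clips per behavior class; 5 planted anomalies."""
    counts = {b: 60 for b in BEHAVIOR_CLASSES}
    counts.update({"anomaly_freeze": 2, "anomaly_jump": 2, "anomaly_limb": 1})
    return SyntheticDatasetSpec(counts=counts, train_ratio=5 / 6, seed=seed)


def run_anomaly_benchmark(
    seed: int,
    epochs: int = 100,
    channels: tuple[int, ...] = (12, 24),
    strides: tuple[int, ...] = (1, 2),
    batch_size: int = 50,
    lr_decay_epochs: tuple[int, ...] = (80,),
) -> dict:
    """Train on normal behavior, detect planted anomalies; return metrics."""
    train_ds, test_ds, truth = generate_dataset(benchmark_data_spec(seed))
    clf = STGCNClassifier(
        channels=channels,
        strides=strides,
        epochs=epochs,
        batch_size=batch_size,
        lr_decay_epochs=lr_decay_epochs,
        seed=seed,
    )
    clf.fit(train_ds.stack(), train_ds.labels)

    X_test = test_ds.stack()
    embeddings = clf.transform(X_test)
    report = detect_abnormal(embeddings)
    pr = average_precision(report.scores, truth)

    normal = ~truth
    probs = clf.predict_proba(X_test[normal])
    enc = np.searchsorted(clf.classes_, test_ds.labels[normal])
    k5 = min(5, probs.shape[1])
    return {
        "seed": seed,
        "n_train": len(train_ds),
        "n_test": len(test_ds),
        "n_anomalies": int(truth.sum()),
        "train_top1": clf.history_.train_top1[-1],
        "test_top1": topk_accuracy(probs, enc, 1),
        "test_top5": topk_accuracy(probs, enc, k5),
        "anomaly_ap": pr.ap,
        "num_flagged": report.num_abnormal,
        "flags_exact": bool(np.array_equal(report.is_abnormal, truth)),
        "num_clusters": report.num_clusters,
        "eps": report.eps,
        "report": report,
        "truth": truth,
    }
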