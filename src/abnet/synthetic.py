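"""Synthetic mouse skeleton clips with class-specific kinematics.

Generates 50-frame, 12-joint top-view keypoint clips for the four
behavior classes the detector is trained on — movement (straight-line
locomotion), head turning (static body, head swinging about the neck),
standing (rearing against a barrier: forepaws elevated, body foreshortened),
and turning (the whole spine changes heading) — plus planted anomaly
families used only for evaluation:

``anomaly_freeze``
    zero centroid motion with high-frequency, large-amplitude tremor.
``anomaly_jump``
    erratic heavy-tailed centroid displacements frame to frame.
``anomaly_limb``
    one forepaw decoupled from the body frame, wandering independently.

Clips are animated from an invented top-view template skeleton (relative
joint offsets in pixels) with i.i.d. Gaussian observation jitter per
joint per frame; temporal smoothness comes from the kinematic templates,
not the noise.  Confidence values are drawn high (Beta(9, 1)), as a
well-trained pose estimator would produce.  Everything is reproducible
from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ClipDataset, MOUSE_KEYPOINTS, SkeletonSequence, normalize_coordinates

__all__ = [
    "BehaviorSpec",
    "SyntheticDatasetSpec",
    "BEHAVIOR_CLASSES",
    "ANOMALY_CLASSES",
    "generate_behavior_clip",
    "generate_dataset",
]

BEHAVIOR_CLASSES: tuple[str, ...] = ("movement", "head_turning", "standing", "turning")
ANOMALY_CLASSES: tuple[str, ...] = ("anomaly_freeze", "anomaly_jump", "anomaly_limb")

# Top-view template: (dx, dy) pixel offsets from the body centroid, x along
# the body axis (nose positive), mouse ~88 px long in a 640x480 frame.
_TEMPLATE: dict[str, tuple[float, float]] = {
    "nose": (44.0, 0.0),
    "head": (32.0, 0.0),
    "L_ear": (30.0, -9.0),
    "R_ear": (30.0, 9.0),
    "neck": (20.0, 0.0),
    "L_forepaw": (14.0, -12.0),
    "R_forepaw": (14.0, 12.0),
    "spine_mid": (0.0, 0.0),
    "L_hindpaw": (-10.0, -13.0),
    "R_hindpaw": (-10.0, 13.0),
    "tail_base": (-22.0, 0.0),
    "tail_tip": (-44.0, 0.0),
}
_HEAD_JOINTS = ("nose", "head", "L_ear", "R_ear")
_NECK_PIVOT = "neck"


@dataclass
class BehaviorSpec:
    """Kinematic parameters of one generated clip."""

    behavior: str = "movement"
    T: int = 50
    frame_size: tuple[float, float] = (640.0, 480.0)
    speed: float = 4.0  # px/frame centroid speed (movement)
    turn_rate: float = 0.05  # rad/frame heading change (turning)
    head_amplitude: float = 1.1  # rad head swing about the neck (head_turning)
    rear_amplitude: float = 0.45  # fractional foreshortening when rearing
    jitter_sd: float = 1.0  # px observation noise per joint per frame
    tremor_sd: float = 6.0  # px tremor for anomaly_freeze
    jump_scale: float = 18.0  # heavy-tail scale for anomaly_jump

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("clip length T must be >= 2")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if self.behavior not in BEHAVIOR_CLASSES + ANOMALY_CLASSES:
            raise ValueError(f"unknown behavior tag: {self.behavior!r}")


@dataclass
class SyntheticDatasetSpec:
    """Counts, anomaly fraction, split ratio and seed for a full dataset."""

    counts: dict[str, int] = field(
        default_factory=lambda: {b: 50 for b in BEHAVIOR_CLASSES}
    )
    anomaly_fraction: float = 0.1
    train_ratio: float = 0.8
    clip_len: int = 50
    frame_size: tuple[float, float] = (640.0, 480.0)
    jitter_sd: float = 1.0
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.anomaly_fraction < 1.0):
            raise ValueError("anomaly fraction must be in [0, 1)")
        if not (0.0 < self.train_ratio < 1.0):
            raise ValueError("train ratio must be in (0, 1)")


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _render(
    centroids: np.ndarray,  # (T, 2)
    headings: np.ndarray,  # (T,)
    spec: BehaviorSpec,
    rng: np.random.Generator,
    head_angle: np.ndarray | None = None,  # (T,) extra head rotation
    rear_factor: np.ndarray | None = None,  # (T,) front foreshortening in [0,1]
    loose_joint: str | None = None,
    loose_path: np.ndarray | None = None,
) -> SkeletonSequence:
    T = spec.T
    V = len(MOUSE_KEYPOINTS)
    data = np.zeros((1, 3, T, V, 1))
    pivot = np.array(_TEMPLATE[_NECK_PIVOT])
    for t in range(T):
        R = _rot(headings[t])
        for v, name in enumerate(MOUSE_KEYPOINTS):
            off = np.array(_TEMPLATE[name])
            if rear_factor is not None and off[0] > 0:
                # rearing: front of the body foreshortens toward the centroid
                off = off * (1.0 - rear_factor[t] * (off[0] / _TEMPLATE["nose"][0]))
            if head_angle is not None and name in _HEAD_JOINTS:
                off = pivot + _rot(head_angle[t]) @ (off - pivot)
            pos = centroids[t] + R @ off
            if loose_joint == name and loose_path is not None:
                pos = loose_path[t]
            data[0, 0, t, v, 0] = pos[0]
            data[0, 1, t, v, 0] = pos[1]
    if spec.jitter_sd > 0:
        data[0, :2] += rng.normal(0.0, spec.jitter_sd, size=data[0, :2].shape)
    data[0, 2] = rng.beta(9.0, 1.0, size=(T, V, 1))
    return SkeletonSequence(data, frame_size=spec.frame_size)


def generate_behavior_clip(spec: BehaviorSpec, rng: np.random.Generator) -> SkeletonSequence:
    """One ``(1, 3, T, 12, 1)`` clip animated per the behavior tag."""
    T = spec.T
    W, H = spec.frame_size
    margin = 80.0
    center = np.array(
        [rng.uniform(margin, W - margin), rng.uniform(margin, H - margin)]
    )
    heading0 = rng.uniform(0, 2 * np.pi)
    t_axis = np.arange(T)

    if spec.behavior == "movement":
        direction = np.array([np.cos(heading0), np.sin(heading0)])
        start = center - direction * spec.speed * T / 2
        centroids = start[None, :] + direction[None, :] * (spec.speed * t_axis)[:, None]
        headings = np.full(T, heading0)
        return _render(centroids, headings, spec, rng)

    if spec.behavior == "head_turning":
        centroids = np.tile(center, (T, 1))
        headings = np.full(T, heading0)
        phase = rng.uniform(0, 2 * np.pi)
        head_angle = spec.head_amplitude * np.sin(
            2 * np.pi * t_axis / T + phase
        )
        return _render(centroids, headings, spec, rng, head_angle=head_angle)

    if spec.behavior == "standing":
        centroids = np.tile(center, (T, 1))
        headings = np.full(T, heading0)
        # rise against the barrier and hold
        ramp = np.clip(t_axis / (T / 4), 0.0, 1.0)
        rear = spec.rear_amplitude * ramp
        return _render(centroids, headings, spec, rng, rear_factor=rear)

    if spec.behavior == "turning":
        headings = heading0 + spec.turn_rate * t_axis
        # slow drift along the arc while the spine heading changes
        centroids = np.tile(center, (T, 1))
        return _render(centroids, headings, spec, rng)

    if spec.behavior == "anomaly_freeze":
        centroids = np.tile(center, (T, 1))
        headings = np.full(T, heading0)
        clip = _render(centroids, headings, spec, rng)
        clip.data[0, :2] += rng.normal(0.0, spec.tremor_sd, size=clip.data[0, :2].shape)
        return clip

    if spec.behavior == "anomaly_jump":
        steps = spec.jump_scale * rng.standard_t(df=1.5, size=(T, 2))
        steps = np.clip(steps, -120.0, 120.0)
        centroids = center[None, :] + np.cumsum(steps, axis=0)
        centroids[:, 0] = np.clip(centroids[:, 0], margin / 2, W - margin / 2)
        centroids[:, 1] = np.clip(centroids[:, 1], margin / 2, H - margin / 2)
        headings = heading0 + np.cumsum(rng.normal(0, 0.6, size=T))
        return _render(centroids, headings, spec, rng)

    if spec.behavior == "anomaly_limb":
        centroids = np.tile(center, (T, 1))
        headings = np.full(T, heading0)
        walk = np.cumsum(rng.normal(0, 10.0, size=(T, 2)), axis=0)
        loose = center[None, :] + np.array([60.0, 60.0]) + walk
        return _render(
            centroids, headings, spec, rng, loose_joint="L_forepaw", loose_path=loose
        )

    raise ValueError(f"unknown behavior tag: {spec.behavior!r}")  # pragma: no cover


def _stratified_split(
    n: int, train_ratio: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_train = int(round(n * train_ratio))
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def generate_dataset(
    spec: SyntheticDatasetSpec,
) -> tuple[ClipDataset, ClipDataset, np.ndarray]:
    """Labeled train/test clip datasets plus per-test-clip anomaly truth.

    Normal classes are split stratified ``train_ratio : 1-train_ratio``.
    Anomalies are planted only in the test split (the detector trains on
    normal behavior exclusively); their count is ``anomaly_fraction``
    of the total normal count, drawn round-robin from the anomaly
    families.  Returns ``(train, test, truth)`` where ``truth[i]`` marks
    test clip ``i`` as a planted anomaly.
    """
    total_normal = sum(spec.counts.get(b, 0) for b in BEHAVIOR_CLASSES)
    if total_normal + sum(
        v for k, v in spec.counts.items() if k in ANOMALY_CLASSES
    ) < 10:
        raise ValueError("dataset too small: need >= 10 clips total")
    rng = np.random.default_rng(spec.seed)

    def make(behavior: str, n: int) -> list[SkeletonSequence]:
        clips = []
        for _ in range(n):
            b = BehaviorSpec(
                behavior=behavior,
                T=spec.clip_len,
                frame_size=spec.frame_size,
                jitter_sd=spec.jitter_sd,
            )
            clip = generate_behavior_clip(b, rng)
            if spec.normalize:
                clip = normalize_coordinates(clip, *spec.frame_size)
            clips.append(clip)
        return clips

    train_clips: list[SkeletonSequence] = []
    train_labels: list[int] = []
    test_clips: list[SkeletonSequence] = []
    test_labels: list[int] = []
    truth: list[bool] = []

    for ci, behavior in enumerate(BEHAVIOR_CLASSES):
        n = spec.counts.get(behavior, 0)
        clips = make(behavior, n)
        tr_idx, te_idx = _stratified_split(n, spec.train_ratio, rng)
        train_clips += [clips[i] for i in tr_idx]
        train_labels += [ci] * len(tr_idx)
        test_clips += [clips[i] for i in te_idx]
        test_labels += [ci] * len(te_idx)
        truth += [False] * len(te_idx)

    n_anom = int(round(spec.anomaly_fraction * total_normal))
    explicit = {k: v for k, v in spec.counts.items() if k in ANOMALY_CLASSES}
    anom_plan: list[str] = []
    if explicit:
        for k, v in explicit.items():
            anom_plan += [k] * v
    else:
        for i in range(n_anom):
            anom_plan.append(ANOMALY_CLASSES[i % len(ANOMALY_CLASSES)])
    anomaly_label = len(BEHAVIOR_CLASSES)
    for behavior in anom_plan:
        test_clips += make(behavior, 1)
        test_labels.append(anomaly_label)
        truth.append(True)

    label_names = BEHAVIOR_CLASSES + ("anomaly",)
    train = ClipDataset(
        clips=train_clips,
        labels=np.array(train_labels, dtype=np.int64),
        label_names=label_names,
        split_tag="train",
    )
    test = ClipDataset(
        clips=test_clips,
        labels=np.array(test_labels, dtype=np.int64),
        label_names=label_names,
        split_tag="test",
    )
    return train, test, np.array(truth, dtype=bool)
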