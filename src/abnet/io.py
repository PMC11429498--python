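"""Keypoint trajectory containers and file formats.

The whole package works on rank-5 skeleton tensors laid out as
``(N, C, T, V, M)``: clip, channel, frame, joint, animal.  Channels are
``x``, ``y``, ``conf`` in that order — image-plane coordinates plus the
pose estimator's per-joint likelihood.  ``M`` is the number of tracked
animals and is 1 throughout (single-housed mouse recordings).

Trajectories come in as DeepLabCut CSV exports (three header rows:
scorer / bodyparts / coords, then one row per frame) and are persisted as
a single ``.npz`` archive holding the stacked clip tensor, labels and a
JSON metadata sidecar.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SkeletonSequence",
    "ClipDataset",
    "MOUSE_KEYPOINTS",
    "read_dlc_csv",
    "write_dlc_csv",
    "normalize_coordinates",
    "segment_clips",
    "write_dataset",
    "read_dataset",
]

#: Default 12-joint top-view mouse skeleton, nose to tail tip.
MOUSE_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "head",
    "L_ear",
    "R_ear",
    "neck",
    "L_forepaw",
    "R_forepaw",
    "spine_mid",
    "L_hindpaw",
    "R_hindpaw",
    "tail_base",
    "tail_tip",
)

CHANNEL_NAMES: tuple[str, str, str] = ("x", "y", "conf")


class FormatError(ValueError):
    """A file does not follow the expected dialect or archive layout."""


@dataclass
class SkeletonSequence:
    """A batch of keypoint trajectories as an ``(N, C, T, V, M)`` tensor.

    Parameters
    ----------
    data:
        float array of shape ``(N, 3, T, V, M)``; channels x, y, conf.
    keypoint_names:
        ordered joint labels, length ``V``.
    fps:
        frames per second of the source video (metadata only).
    frame_size:
        ``(width, height)`` in pixels of the source frame, recorded by
        :func:`normalize_coordinates` so pixel-scale augmentation can be
        converted to normalized units later.
    normalized:
        True once coordinates have been mapped to ``[-1, 1]``.
    """

    data: np.ndarray
    keypoint_names: Sequence[str] = MOUSE_KEYPOINTS
    channel_names: Sequence[str] = CHANNEL_NAMES
    fps: float | None = None
    frame_size: tuple[float, float] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 5:
            raise ValueError(
                f"skeleton tensor must be rank 5 (N, C, T, V, M), got shape {arr.shape}"
            )
        if arr.shape[1] != 3:
            raise ValueError(f"expected 3 channels (x, y, conf), got {arr.shape[1]}")
        if arr.shape[3] != len(self.keypoint_names):
            raise ValueError(
                f"joint axis {arr.shape[3]} does not match "
                f"{len(self.keypoint_names)} keypoint names"
            )
        conf = arr[:, 2]
        if conf.size and (conf.min() < -1e-9 or conf.max() > 1 + 1e-9):
            raise ValueError("conf channel must lie in [0, 1]")
        self.data = arr

    @property
    def n_clips(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def n_joints(self) -> int:
        return self.data.shape[3]

    def copy(self) -> "SkeletonSequence":
        return replace(self, data=self.data.copy())


@dataclass
class ClipDataset:
    """Fixed-length clips plus optional integer behavior labels."""

    clips: list[SkeletonSequence]
    labels: np.ndarray | None = None
    label_names: Sequence[str] = ()
    split_tag: str = ""

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.clips):
                raise ValueError("one label per clip required")
            if self.label_names and self.labels.size:
                if self.labels.min() < 0 or self.labels.max() >= len(self.label_names):
                    raise ValueError("labels reference invalid label_names indices")
        shapes = {c.data.shape[1:] for c in self.clips}
        if len(shapes) > 1:
            raise ValueError(f"clips disagree on (C, T, V, M): {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.clips)

    def stack(self) -> np.ndarray:
        """All clips as one ``(n_clips, 3, T, V, M)`` array."""
        if not self.clips:
            return np.zeros((0, 3, 0, len(MOUSE_KEYPOINTS), 1))
        return np.concatenate([c.data for c in self.clips], axis=0)

    def subset(self, idx: Sequence[int], split_tag: str | None = None) -> "ClipDataset":
        idx = list(idx)
        return ClipDataset(
            clips=[self.clips[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            label_names=self.label_names,
            split_tag=self.split_tag if split_tag is None else split_tag,
        )


# ---------------------------------------------------------------------------
# DeepLabCut CSV dialect
# ---------------------------------------------------------------------------

def read_dlc_csv(path, keypoint_names: Sequence[str] = MOUSE_KEYPOINTS) -> SkeletonSequence:
    """Read a DeepLabCut CSV export into a single-clip skeleton tensor.

    The dialect has three header rows (scorer, bodyparts, coords) and one
    data row per frame; every requested joint must provide x, y and
    likelihood columns.  Likelihood is mapped to the conf channel.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # malformed header or unreadable file
        raise FormatError(f"not a DeepLabCut CSV: {exc}") from exc

    # column index: (scorer, bodypart, coord)
    bodyparts = {c[1] for c in df.columns}
    T = len(df)
    V = len(keypoint_names)
    out = np.zeros((1, 3, T, V, 1), dtype=np.float64)
    for v, joint in enumerate(keypoint_names):
        if joint not in bodyparts:
            raise FormatError(f"joint column missing from CSV: {joint!r}")
        for ci, coord in enumerate(("x", "y", "likelihood")):
            cols = [c for c in df.columns if c[1] == joint and c[2] == coord]
            if not cols:
                raise FormatError(f"column {coord!r} missing for joint {joint!r}")
            series = pd.to_numeric(df[cols[0]], errors="coerce")
            if series.isna().any():
                row = int(series.index[series.isna()][0])
                raise FormatError(
                    f"non-numeric value for {joint}/{coord} at frame row {row}"
                )
            out[0, ci, :, v, 0] = series.to_numpy(dtype=np.float64)
    np.clip(out[:, 2], 0.0, 1.0, out=out[:, 2])
    return SkeletonSequence(out, keypoint_names=tuple(keypoint_names))


def write_dlc_csv(seq: SkeletonSequence, path, scorer: str = "abnet") -> None:
    """Write a single-clip sequence in the DeepLabCut three-header dialect."""
    if seq.n_clips != 1:
        raise ValueError("DLC CSV holds one recording; got a multi-clip batch")
    cols = pd.MultiIndex.from_tuples(
        [
            (scorer, joint, coord)
            for joint in seq.keypoint_names
            for coord in ("x", "y", "likelihood")
        ],
        names=["scorer", "bodyparts", "coords"],
    )
    T = seq.n_frames
    mat = np.empty((T, 3 * seq.n_joints), dtype=np.float64)
    for v in range(seq.n_joints):
        for ci in range(3):
            mat[:, 3 * v + ci] = seq.data[0, ci, :, v, 0]
    df = pd.DataFrame(mat, columns=cols)
    df.index.name = None
    df.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# Coordinate normalization and clip segmentation
# ---------------------------------------------------------------------------

def normalize_coordinates(
    seq: SkeletonSequence, frame_width: float, frame_height: float
) -> SkeletonSequence:
    """Map pixel coordinates into ``[-1, 1]`` with a single shared scale.

    Coordinates are centered on the frame midpoint and divided by half the
    larger frame dimension, so the aspect ratio is preserved.  The conf
    channel is untouched.  The frame size is recorded on the result so
    later pixel-denominated operations (±5 px augmentation shifts) can be
    converted to normalized units.
    """
    if frame_width <= 0 or frame_height <= 0:
        raise ValueError("frame dimensions must be positive")
    scale = max(frame_width, frame_height) / 2.0
    out = seq.data.copy()
    out[:, 0] = (out[:, 0] - frame_width / 2.0) / scale
    out[:, 1] = (out[:, 1] - frame_height / 2.0) / scale
    return replace(
        seq,
        data=out,
        frame_size=(float(frame_width), float(frame_height)),
        normalized=True,
    )


def align_egocentric(
    data: np.ndarray,
    origin_joint: int = 7,
    anterior_joint: int = 4,
    posterior_joint: int = 10,
    n_ref_frames: int = 5,
) -> np.ndarray:
    """Rigidly align each clip to its initial egocentric body frame.

    For every clip, the initial position of ``origin_joint`` (default
    spine_mid) is moved to the origin and all frames are rotated so the
    initial body axis (``posterior_joint`` → ``anterior_joint``, default
    tail_base → neck) points along +x.  "Initial" means averaged over the
    first ``n_ref_frames`` frames, which suppresses per-frame keypoint
    jitter in the reference without meaningfully biasing it.  The
    transform is rigid and shared by all frames of a clip, so within-clip
    motion — translation, rotation, posture change — is fully preserved
    while the arbitrary starting position and heading of the animal are
    removed.  Standard egocentric preprocessing for pose-based behavior
    analysis.

    Accepts and returns an ``(N, C, T, V, M)`` array; channels beyond
    x, y are untouched.
    """
    arr = np.asarray(data, dtype=np.float64).copy()
    if arr.ndim != 5:
        raise ValueError("expected rank-5 tensor (N, C, T, V, M)")
    r = max(1, min(n_ref_frames, arr.shape[2]))
    for n in range(arr.shape[0]):
        for m in range(arr.shape[4]):
            ox = arr[n, 0, :r, origin_joint, m].mean()
            oy = arr[n, 1, :r, origin_joint, m].mean()
            ax = arr[n, 0, :r, anterior_joint, m].mean() - arr[n, 0, :r, posterior_joint, m].mean()
            ay = arr[n, 1, :r, anterior_joint, m].mean() - arr[n, 1, :r, posterior_joint, m].mean()
            theta = np.arctan2(ay, ax)
            c, s = np.cos(-theta), np.sin(-theta)
            x = arr[n, 0, :, :, m] - ox
            y = arr[n, 1, :, :, m] - oy
            arr[n, 0, :, :, m] = c * x - s * y
            arr[n, 1, :, :, m] = s * x + c * y
    return arr


def segment_clips(seq: SkeletonSequence, clip_len: int = 50) -> ClipDataset:
    """Cut a recording into consecutive non-overlapping ``clip_len``-frame clips.

    The trailing remainder shorter than ``clip_len`` is dropped, so the
    number of clips is ``floor(T / clip_len)``.
    """
    if clip_len < 1:
        raise ValueError("clip_len must be >= 1")
    n = seq.n_frames // clip_len
    clips = []
    for i in range(n):
        window = seq.data[:, :, i * clip_len : (i + 1) * clip_len]
        for b in range(window.shape[0]):
            clips.append(replace(seq, data=window[b : b + 1].copy()))
    return ClipDataset(clips=clips)


# ---------------------------------------------------------------------------
# Dataset archive (.npz + JSON sidecar inside the archive)
# ---------------------------------------------------------------------------

def write_dataset(ds: ClipDataset, path) -> None:
    """Persist a dataset as one ``.npz`` archive (tensor, labels, metadata)."""
    path = Path(path)
    meta = {
        "keypoint_names": list(ds.clips[0].keypoint_names) if ds.clips else list(MOUSE_KEYPOINTS),
        "label_names": list(ds.label_names),
        "split_tag": ds.split_tag,
        "fps": ds.clips[0].fps if ds.clips else None,
        "frame_size": list(ds.clips[0].frame_size) if ds.clips and ds.clips[0].frame_size else None,
        "normalized": bool(ds.clips[0].normalized) if ds.clips else False,
    }
    tensor = ds.stack()
    labels = ds.labels if ds.labels is not None else np.array([], dtype=np.int64)
    has_labels = ds.labels is not None
    # canonical serialization: fixed key order, deterministic JSON
    buf = _stdio.BytesIO()
    np.savez(
        buf,
        tensor=tensor,
        labels=labels,
        has_labels=np.array(has_labels),
        meta=np.frombuffer(
            json.dumps(meta, sort_keys=True).encode("utf-8"), dtype=np.uint8
        ),
    )
    path.write_bytes(buf.getvalue())


def read_dataset(path) -> ClipDataset:
    """Load a dataset archive written by :func:`write_dataset`."""
    try:
        with np.load(path) as npz:
            tensor = npz["tensor"]
            labels = npz["labels"]
            has_labels = bool(npz["has_labels"])
            meta = json.loads(bytes(npz["meta"].tobytes()).decode("utf-8"))
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"corrupt or foreign dataset archive: {exc}") from exc
    frame_size = meta.get("frame_size")
    clips = [
        SkeletonSequence(
            tensor[i : i + 1],
            keypoint_names=tuple(meta["keypoint_names"]),
            fps=meta.get("fps"),
            frame_size=tuple(frame_size) if frame_size else None,
            normalized=meta.get("normalized", False),
        )
        for i in range(tensor.shape[0])
    ]
    return ClipDataset(
        clips=clips,
        labels=labels if has_labels else None,
        label_names=tuple(meta["label_names"]),
        split_tag=meta.get("split_tag", ""),
    )
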