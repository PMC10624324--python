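"""Reading, validation and cleaning of BODY_25 pose-keypoint time series.

The input dialect is the OpenPose per-frame JSON: a top-level ``"people"``
array in which each person carries a flat ``"pose_keypoints_2d"`` list of
75 numbers (25 keypoints x [x, y, confidence]).  Image coordinates follow
the usual convention: origin at the top-left corner, y increasing downward.

A keypoint is flagged *missing* when its confidence falls below the
missing-threshold or when its coordinates are exactly (0, 0) — the value
OpenPose emits for undetected joints.  Missing coordinates are never
consumed by downstream kinematics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyFrameError,
    FormatError,
    InsufficientDataError,
)

#: BODY_25 keypoint names, index 0..24.
BODY25_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

N_KEYPOINTS = 25

#: Confidence below which a keypoint is treated as undetected.
DEFAULT_MISSING_THRESHOLD = 0.1

#: Longest gap (in frames) bridged by linear interpolation; ~167 ms at 30 fps.
DEFAULT_MAX_GAP_FRAMES = 5

DEFAULT_FPS = 30.0

TESTS = ("SLST", "SDT")
LIMBS = ("left", "right", "unspecified")


@dataclass(frozen=True)
class Keypoint:
    """One 2D landmark estimate with its detector confidence."""

    x: float
    y: float
    confidence: float
    missing: bool = False


@dataclass
class PoseFrame:
    """A single 25-keypoint skeleton observation.

    ``xy`` is a (25, 2) array of pixel coordinates, ``confidence`` a (25,)
    array in [0, 1] and ``missing`` a (25,) boolean mask.  All 25 slots are
    always present; undetected joints are flagged, never absent.
    """

    xy: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(N_KEYPOINTS, 2)
        self.confidence = np.asarray(self.confidence, dtype=float).reshape(N_KEYPOINTS)
        self.missing = np.asarray(self.missing, dtype=bool).reshape(N_KEYPOINTS)

    def keypoint(self, index: int) -> Keypoint:
        return Keypoint(
            x=float(self.xy[index, 0]),
            y=float(self.xy[index, 1]),
            confidence=float(self.confidence[index]),
            missing=bool(self.missing[index]),
        )


@dataclass
class CleaningReport:
    """What happened to a sequence during reading / gap filling."""

    dropped_frames: list[int] = field(default_factory=list)
    filled: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    unfilled: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def n_filled(self) -> int:
        return sum(b - a + 1 for runs in self.filled.values() for a, b in runs)

    @property
    def n_unfilled(self) -> int:
        return sum(b - a + 1 for runs in self.unfilled.values() for a, b in runs)


@dataclass
class PoseSequence:
    """Time-ordered skeleton frames for one recording (subject x test).

    The canonical store is array-based: ``xy`` has shape (n_frames, 25, 2),
    ``confidence`` and ``missing`` shape (n_frames, 25).  ``frame_indices``
    keeps the original ordinals so timestamps reflect dropped frames.
    """

    xy: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    frame_indices: np.ndarray
    fps: float = DEFAULT_FPS
    subject_id: str = "anonymous"
    test_id: str = "SLST"
    limb: str = "unspecified"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.xy.ndim != 3 or self.xy.shape[1:] != (N_KEYPOINTS, 2):
            raise ValueError(f"xy must have shape (n, 25, 2), got {self.xy.shape}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.test_id not in TESTS:
            raise ValueError(f"test_id must be one of {TESTS}, got {self.test_id!r}")
        if self.limb not in LIMBS:
            raise ValueError(f"limb must be one of {LIMBS}, got {self.limb!r}")

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    @property
    def timestamps(self) -> np.ndarray:
        return self.frame_indices / self.fps

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}:{self.test_id}:{self.limb}"

    def frame(self, i: int) -> PoseFrame:
        return PoseFrame(
            xy=self.xy[i],
            confidence=self.confidence[i],
            missing=self.missing[i],
            frame_index=int(self.frame_indices[i]),
        )

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            xy=self.xy.copy(),
            confidence=self.confidence.copy(),
            missing=self.missing.copy(),
            frame_indices=self.frame_indices.copy(),
        )


# ---------------------------------------------------------------------------
# Frame-document parsing
# ---------------------------------------------------------------------------

def _person_keypoints(person: dict, position: int) -> np.ndarray:
    if not isinstance(person, dict):
        raise FormatError(f"people[{position}] is not an object")
    try:
        flat = person["pose_keypoints_2d"]
    except (KeyError, TypeError):
        raise FormatError(
            f"people[{position}] lacks key 'pose_keypoints_2d'"
        ) from None
    if not isinstance(flat, (list, tuple)) or len(flat) != 3 * N_KEYPOINTS:
        raise FormatError(
            "'pose_keypoints_2d' must be a flat list of 75 numbers, "
            f"got length {len(flat) if isinstance(flat, (list, tuple)) else 'n/a'}"
        )
    try:
        arr = np.asarray(flat, dtype=float).reshape(N_KEYPOINTS, 3)
    except (TypeError, ValueError):
        raise FormatError("'pose_keypoints_2d' contains non-numeric entries") from None
    if not np.all(np.isfinite(arr)):
        raise FormatError("'pose_keypoints_2d' contains non-finite values")
    return arr


def read_openpose_frame(
    frame_document: dict,
    person_policy: str = "best_mean_confidence",
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
    frame_index: int = 0,
) -> PoseFrame:
    """Parse one OpenPose frame document into a :class:`PoseFrame`.

    When several people are present the ``person_policy`` decides which
    skeleton to keep: ``"best_mean_confidence"`` (default) selects the
    person whose keypoints have the highest mean confidence, ``"first"``
    keeps the first listed.

    Raises
    ------
    FormatError
        If the document does not follow the dialect; the message names the
        offending key.
    EmptyFrameError
        If the ``people`` array is empty (callers may drop the frame).
    """
    if not isinstance(frame_document, dict):
        raise FormatError("frame document is not a JSON object")
    try:
        people = frame_document["people"]
    except KeyError:
        raise FormatError("frame document lacks key 'people'") from None
    if not isinstance(people, list):
        raise FormatError("'people' is not an array")
    if len(people) == 0:
        raise EmptyFrameError(f"frame {frame_index}: no person detected")

    candidates = [_person_keypoints(p, i) for i, p in enumerate(people)]
    if person_policy == "best_mean_confidence":
        # argmax keeps the first person on exact ties -> deterministic
        chosen = candidates[int(np.argmax([c[:, 2].mean() for c in candidates]))]
    elif person_policy == "first":
        chosen = candidates[0]
    else:
        raise ValueError(f"unknown person_policy {person_policy!r}")

    xy = chosen[:, :2]
    conf = chosen[:, 2]
    missing = (conf < missing_threshold) | ((xy[:, 0] == 0.0) & (xy[:, 1] == 0.0))
    return PoseFrame(xy=xy, confidence=conf, missing=missing, frame_index=frame_index)


def read_sequence(
    frame_documents: Iterable[dict],
    fps: float = DEFAULT_FPS,
    subject_id: str = "anonymous",
    test_id: str = "SLST",
    limb: str = "unspecified",
    person_policy: str = "best_mean_confidence",
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> tuple[PoseSequence, CleaningReport]:
    """Assemble an ordered collection of frame documents into a sequence.

    Empty frames (no detected person) are dropped and recorded in the
    cleaning report; at least two usable frames are required.
    """
    report = CleaningReport()
    frames: list[PoseFrame] = []
    for i, doc in enumerate(frame_documents):
        try:
            frames.append(
                read_openpose_frame(
                    doc,
                    person_policy=person_policy,
                    missing_threshold=missing_threshold,
                    frame_index=i,
                )
            )
        except EmptyFrameError:
            report.dropped_frames.append(i)
    if len(frames) < 2:
        raise InsufficientDataError(
            f"need at least 2 usable frames, got {len(frames)} "
            f"({len(report.dropped_frames)} dropped)"
        )
    seq = PoseSequence(
        xy=np.stack([f.xy for f in frames]),
        confidence=np.stack([f.confidence for f in frames]),
        missing=np.stack([f.missing for f in frames]),
        frame_indices=np.array([f.frame_index for f in frames]),
        fps=fps,
        subject_id=subject_id,
        test_id=test_id,
        limb=limb,
    )
    return seq, report


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in a 1-D boolean mask, as (start, stop) inclusive."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def fill_missing(
    seq: PoseSequence,
    max_gap_frames: int = DEFAULT_MAX_GAP_FRAMES,
) -> tuple[PoseSequence, CleaningReport]:
    """Linearly interpolate short keypoint dropouts.

    Gaps of at most ``max_gap_frames`` original frames, bounded on both
    sides by observed values, are filled per coordinate (and confidence);
    longer or boundary gaps stay missing and are listed in the report.
    The operation is idempotent and leaves fully observed sequences
    bitwise identical.
    """
    report = CleaningReport()
    if not seq.missing.any():
        return seq, report
    out = seq.copy()
    idx = seq.frame_indices
    for k in range(N_KEYPOINTS):
        mask = seq.missing[:, k]
        if not mask.any():
            continue
        for a, b in _missing_runs(mask):
            # gap length measured in original frame ordinals
            bounded = a > 0 and b < len(seq) - 1
            gap_len = int(idx[min(b + 1, len(seq) - 1)] - idx[max(a - 1, 0)] - 1)
            if bounded and gap_len <= max_gap_frames:
                lo, hi = a - 1, b + 1
                t = (idx[a:b + 1] - idx[lo]) / (idx[hi] - idx[lo])
                for c in range(2):
                    out.xy[a:b + 1, k, c] = (
                        seq.xy[lo, k, c] + t * (seq.xy[hi, k, c] - seq.xy[lo, k, c])
                    )
                out.confidence[a:b + 1, k] = (
                    seq.confidence[lo, k]
                    + t * (seq.confidence[hi, k] - seq.confidence[lo, k])
                )
                out.missing[a:b + 1, k] = False
                report.filled.setdefault(k, []).append((a, b))
            else:
                report.unfilled.setdefault(k, []).append((a, b))
    return out, report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def frame_to_document(seq: PoseSequence, i: int) -> dict:
    """Render frame ``i`` back into the OpenPose frame-document dialect.

    Missing keypoints are written as (0, 0, 0), matching the detector's
    own convention, so flags survive a round trip.
    """
    xy = seq.xy[i].copy()
    conf = seq.confidence[i].copy()
    zero = seq.missing[i] & (conf == 0.0)
    xy[zero] = 0.0
    flat = np.column_stack([xy, conf]).reshape(-1)
    return {"version": 1.3, "people": [{"person_id": [-1],
                                        "pose_keypoints_2d": flat.tolist()}]}


def write_jsonl(seq: PoseSequence, path: str | Path) -> None:
    """Write a sequence as one JSON frame document per line."""
    path = Path(path)
    with path.open("w") as fh:
        for i in range(len(seq)):
            fh.write(json.dumps(frame_to_document(seq, i)) + "\n")


def read_jsonl(
    path: str | Path,
    fps: float = DEFAULT_FPS,
    **metadata,
) -> tuple[PoseSequence, CleaningReport]:
    """Read a JSON-lines file of frame documents."""
    with Path(path).open() as fh:
        docs = [json.loads(line) for line in fh if line.strip()]
    return read_sequence(docs, fps=fps, **metadata)


def write_openpose_dir(seq: PoseSequence, directory: str | Path,
                       prefix: str = "frame") -> None:
    """Write one ``*_keypoints.json`` file per frame, the standard layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(len(seq)):
        name = f"{prefix}_{int(seq.frame_indices[i]):012d}_keypoints.json"
        (directory / name).write_text(json.dumps(frame_to_document(seq, i)))


def read_openpose_dir(
    directory: str | Path,
    fps: float = DEFAULT_FPS,
    **metadata,
) -> tuple[PoseSequence, CleaningReport]:
    """Read a directory of per-frame ``*_keypoints.json`` files, sorted by name."""
    files = sorted(Path(directory).glob("*_keypoints.json"))
    if not files:
        raise InsufficientDataError(f"no *_keypoints.json files in {directory}")
    docs = [json.loads(f.read_text()) for f in files]
    return read_sequence(docs, fps=fps, **metadata)


def sequence_to_tidy(seq: PoseSequence) -> pd.DataFrame:
    """Tidy long-format view: frame, keypoint_index, x, y, confidence, missing."""
    n = len(seq)
    return pd.DataFrame({
        "frame": np.repeat(seq.frame_indices, N_KEYPOINTS),
        "keypoint_index": np.tile(np.arange(N_KEYPOINTS), n),
        "keypoint": np.tile(np.array(BODY25_NAMES), n),
        "x": seq.xy[:, :, 0].reshape(-1),
        "y": seq.xy[:, :, 1].reshape(-1),
        "confidence": seq.confidence.reshape(-1),
        "missing": seq.missing.reshape(-1),
    })
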