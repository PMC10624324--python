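"""Kinematic signals from 2D skeleton sequences.

Three signal families are computed from BODY_25 keypoints:

* **joint angle** — the interior angle at a vertex keypoint B formed with
  two neighbouring keypoints A and C, ``arccos(BA.BC / |BA||BC|)``, in
  [0, 180] degrees;
* **keypoint-pair orientation** — the angle between the segment joining
  two keypoints and the image horizontal, by quadrant-aware arctangent,
  in (-180, 180] degrees.  Image coordinates (y down) are converted to the
  mathematical convention (y up) first, so "upward on screen" is positive;
* **relative distance** — the Euclidean distance between two keypoints
  divided by the same frame's trunk length (neck to mid-hip, keypoints
  1 and 8).  The normalisation removes body-height and camera-distance
  scale, making the value dimensionless.

The default catalogue lists the 15 signals used for movement-quality
scoring of the Single Leg Squat Test and Step Down Test.  Angles are
degrees externally and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateGeometryError, EmptySignalError
from .pose_io import N_KEYPOINTS, PoseSequence

CATEGORIES = ("joint_angle", "pair_orientation", "relative_distance")

NECK, MIDHIP = 1, 8

#: Trunk lengths at or below this (pixels) are degenerate normalizers.
DEFAULT_TRUNK_EPS = 1.0


@dataclass(frozen=True)
class SignalDef:
    """Named definition of one kinematic signal.

    ``keypoints`` holds 3 BODY_25 indices (A, vertex B, C) for a joint
    angle and 2 for the other categories.
    """

    name: str
    category: str
    keypoints: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"{self.name}: unknown category {self.category!r}"
            )
        arity = 3 if self.category == "joint_angle" else 2
        if len(self.keypoints) != arity:
            raise ConfigurationError(
                f"{self.name}: {self.category} needs {arity} keypoints, "
                f"got {len(self.keypoints)}"
            )
        if len(set(self.keypoints)) != len(self.keypoints):
            raise ConfigurationError(f"{self.name}: keypoint indices must be distinct")
        if any(not (0 <= k < N_KEYPOINTS) for k in self.keypoints):
            raise ConfigurationError(f"{self.name}: keypoint index out of range 0..24")


@dataclass
class Signal:
    """A named per-frame scalar series with a validity mask.

    Values are degrees for the angle categories and dimensionless for
    relative distances; frames where any contributing keypoint is missing
    (or the geometry degenerate) carry NaN and ``valid_mask`` False.
    """

    name: str
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


# ---------------------------------------------------------------------------
# Point-wise primitives (scalar API)
# ---------------------------------------------------------------------------

def joint_angle(a: Sequence[float], b: Sequence[float], c: Sequence[float]) -> float:
    """Interior angle at vertex ``b`` in degrees, in [0, 180].

    The cosine is clamped to [-1, 1] before the arccos so collinear
    configurations do not overshoot through floating-point error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ba = a - b
    bc = c - b
    nba = math.hypot(*ba)
    nbc = math.hypot(*bc)
    if nba == 0.0 or nbc == 0.0:
        raise DegenerateGeometryError("joint_angle: zero-length vector at vertex")
    cosang = float(np.dot(ba, bc)) / (nba * nbc)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def pair_orientation(a: Sequence[float], b: Sequence[float]) -> float:
    """Orientation of the segment A->B against the image horizontal.

    Inputs are image coordinates (y down); the y axis is negated before
    the quadrant-aware arctangent so a pair pointing up on screen reads
    +90 degrees.  Result in (-180, 180].
    """
    dx = float(b[0]) - float(a[0])
    dy = -(float(b[1]) - float(a[1]))
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("pair_orientation: coincident points")
    ang = math.degrees(math.atan2(dy, dx))
    if ang <= -180.0:
        ang += 360.0
    return ang


def relative_distance(
    a: Sequence[float],
    b: Sequence[float],
    neck: Sequence[float],
    midhip: Sequence[float],
    eps: float = DEFAULT_TRUNK_EPS,
) -> float:
    """Distance |AB| normalised by the trunk length |neck midhip|."""
    trunk = math.hypot(float(neck[0]) - float(midhip[0]),
                       float(neck[1]) - float(midhip[1]))
    if trunk <= eps:
        raise DegenerateGeometryError(
            f"relative_distance: trunk length {trunk:.3g} <= eps {eps:.3g}"
        )
    d = math.hypot(float(a[0]) - float(b[0]), float(a[1]) - float(b[1]))
    return d / trunk


# ---------------------------------------------------------------------------
# Sequence-level evaluation
# ---------------------------------------------------------------------------

def compute_signal(
    seq: PoseSequence,
    sdef: SignalDef,
    trunk_normalizer: str = "frame",
    trunk_eps: float = DEFAULT_TRUNK_EPS,
    smooth: bool = False,
    smooth_width: int = 5,
) -> Signal:
    """Evaluate one signal definition over every frame of a sequence.

    Frames where any contributing keypoint is missing — or where the
    geometry degenerates (zero-length vector, trunk shorter than
    ``trunk_eps``) — are marked invalid rather than raising.  For
    relative distances ``trunk_normalizer="median"`` replaces the
    per-frame trunk length with the sequence median of the valid trunk
    lengths, a fallback for noisy trunks.

    Raises
    ------
    EmptySignalError
        If no frame at all is valid.
    """
    idx = list(sdef.keypoints)
    xy = seq.xy
    valid = ~seq.missing[:, idx].any(axis=1)
    n = len(seq)
    values = np.full(n, np.nan)

    if sdef.category == "joint_angle":
        a, b, c = xy[:, idx[0]], xy[:, idx[1]], xy[:, idx[2]]
        ba = a - b
        bc = c - b
        nba = np.linalg.norm(ba, axis=1)
        nbc = np.linalg.norm(bc, axis=1)
        ok = valid & (nba > 0) & (nbc > 0)
        cos = np.zeros(n)
        np.divide(np.einsum("ij,ij->i", ba, bc), nba * nbc, out=cos, where=ok)
        values[ok] = np.degrees(np.arccos(np.clip(cos[ok], -1.0, 1.0)))
        valid = ok
    elif sdef.category == "pair_orientation":
        a, b = xy[:, idx[0]], xy[:, idx[1]]
        dx = b[:, 0] - a[:, 0]
        dy = -(b[:, 1] - a[:, 1])
        ok = valid & ((dx != 0) | (dy != 0))
        ang = np.degrees(np.arctan2(dy, dx))
        ang[ang <= -180.0] += 360.0
        values[ok] = ang[ok]
        valid = ok
    else:  # relative_distance
        a, b = xy[:, idx[0]], xy[:, idx[1]]
        trunk = np.linalg.norm(xy[:, NECK] - xy[:, MIDHIP], axis=1)
        trunk_ok = ~(seq.missing[:, NECK] | seq.missing[:, MIDHIP]) & (trunk > trunk_eps)
        if trunk_normalizer == "median":
            if not trunk_ok.any():
                raise EmptySignalError(
                    f"{sdef.name}: no valid trunk length for median normalizer"
                )
            norm = np.full(n, float(np.median(trunk[trunk_ok])))
            ok = valid
        elif trunk_normalizer == "frame":
            norm = trunk
            ok = valid & trunk_ok
        else:
            raise ConfigurationError(
                f"unknown trunk_normalizer {trunk_normalizer!r}"
            )
        d = np.linalg.norm(a - b, axis=1)
        values[ok] = d[ok] / norm[ok]
        valid = ok

    if not valid.any():
        raise EmptySignalError(f"{sdef.name}: all {n} frames invalid")
    if smooth:
        values = _median_smooth(values, valid, smooth_width)
    return Signal(name=sdef.name, values=values, valid_mask=valid)


def _median_smooth(values: np.ndarray, valid: np.ndarray, width: int) -> np.ndarray:
    """Running median over valid frames only; NaNs pass through."""
    if width % 2 == 0 or width < 1:
        raise ConfigurationError("smooth_width must be a positive odd integer")
    half = width // 2
    out = values.copy()
    n = len(values)
    for i in np.flatnonzero(valid):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        window = values[lo:hi][valid[lo:hi]]
        out[i] = np.median(window)
    return out


def compute_signals(
    seq: PoseSequence,
    catalogue: Iterable[SignalDef] | None = None,
    **kwargs,
) -> dict[str, Signal]:
    """Evaluate a whole catalogue; returns name -> Signal."""
    catalogue = list(catalogue) if catalogue is not None else default_catalogue()
    return {sdef.name: compute_signal(seq, sdef, **kwargs) for sdef in catalogue}


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------

# The published feature list for SLST/SDT scoring.  Index tuples are kept
# exactly as published even where a row name reads loosely against the
# BODY_25 map (e.g. "RWristMidHip" pairing indices 4 and 7); use
# load_catalogue() to override with corrected anatomical definitions.
_DEFAULT_CATALOGUE: tuple[tuple[str, str, tuple[int, ...]], ...] = (
    ("Hips", "pair_orientation", (9, 12)),
    ("BothShoulders", "pair_orientation", (2, 5)),
    ("Spine", "pair_orientation", (1, 8)),
    ("NeckRShoulderRElbow", "joint_angle", (1, 2, 3)),
    ("NeckLShoulderLElbow", "joint_angle", (1, 5, 6)),
    ("MidHipRHipRKnee", "joint_angle", (8, 9, 10)),
    ("MidHipLHipLKnee", "joint_angle", (8, 12, 13)),
    ("RHipRKneeRAnkle", "joint_angle", (9, 10, 11)),
    ("LHipLKneeLAnkle", "joint_angle", (12, 13, 14)),
    ("NoseNeckMidHip", "joint_angle", (0, 1, 8)),
    ("NeckMidHip", "relative_distance", (1, 8)),
    ("RWristMidHip", "relative_distance", (4, 7)),
    ("RWristLWrist", "relative_distance", (4, 8)),
    ("MidHipLSmallToe", "relative_distance", (8, 13)),
    ("MidHipLRSmallToe", "relative_distance", (8, 10)),
)


def default_catalogue() -> list[SignalDef]:
    """The 15 default signal definitions, in canonical order."""
    return [SignalDef(name, cat, kps) for name, cat, kps in _DEFAULT_CATALOGUE]


def load_catalogue(path: str | Path) -> list[SignalDef]:
    """Load a catalogue override: a YAML list of {name, category, keypoints}."""
    with Path(path).open() as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list) or not entries:
        raise ConfigurationError(f"{path}: catalogue must be a non-empty list")
    defs = []
    for e in entries:
        try:
            defs.append(SignalDef(str(e["name"]), str(e["category"]),
                                  tuple(int(k) for k in e["keypoints"])))
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(
                f"{path}: catalogue entry {e!r} malformed ({exc})"
            ) from None
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"{path}: duplicate signal names")
    return defs


def signals_to_tidy(signals: dict[str, Signal], seq: PoseSequence) -> pd.DataFrame:
    """Tidy long-format export: frame, signal, value, valid."""
    rows = []
    for name, sig in signals.items():
        rows.append(pd.DataFrame({
            "frame": seq.frame_indices,
            "signal": name,
            "value": sig.values,
            "valid": sig.valid_mask,
        }))
    return pd.concat(rows, ignore_index=True)
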