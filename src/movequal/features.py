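"""Per-recording feature extraction from kinematic signals.

The primary feature is the range of movement (ROM): the difference between
the maximum and minimum of a signal over its valid frames.  One feature
vector summarises one whole recording; with the default catalogue that is
15 ROM values.  An extended mode appends the four order statistics (min,
max, median, mean) per signal.  Features keep the source signal's units
(degrees or dimensionless) and are deliberately not rescaled: the
downstream tree ensemble is scale-invariant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySignalError, InsufficientDataError
from .kinematics import Signal, SignalDef, compute_signals, default_catalogue
from .pose_io import PoseSequence

MODES = ("rom", "extended")

_STATS = ("min", "max", "median", "mean")


def range_of_movement(signal: Signal) -> float:
    """max - min of the signal over valid frames; always >= 0."""
    v = signal.valid_values
    if v.size == 0:
        raise EmptySignalError(f"{signal.name}: no valid frames for ROM")
    return float(v.max() - v.min())


def signal_statistics(signal: Signal) -> dict[str, float]:
    """The four summary statistics (min, max, median, mean) over valid frames."""
    v = signal.valid_values
    if v.size == 0:
        raise EmptySignalError(f"{signal.name}: no valid frames for statistics")
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.median(v)),
        "mean": float(v.mean()),
    }


@dataclass
class FeatureTable:
    """Rectangular recordings x features matrix with provenance.

    ``frame`` holds columns ``recording_id``, ``subject_id``, ``test_id``
    followed by the features in catalogue order; ``excluded`` lists
    recordings dropped because a signal had no valid frame.
    """

    frame: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        meta = {"recording_id", "subject_id", "test_id"}
        return [c for c in self.frame.columns if c not in meta]

    def matrix(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(frame=pd.read_csv(path))


def feature_columns(catalogue: Sequence[SignalDef], mode: str) -> list[str]:
    """Column names in fixed catalogue order for a given mode."""
    if mode == "rom":
        return [d.name for d in catalogue]
    if mode == "extended":
        cols = []
        for d in catalogue:
            cols.append(d.name)
            cols.extend(f"{d.name}_{s}" for s in _STATS)
        return cols
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def feature_vector(
    signals: dict[str, Signal],
    catalogue: Sequence[SignalDef],
    mode: str = "rom",
) -> dict[str, float]:
    """One recording's features from its computed signals."""
    out: dict[str, float] = {}
    for d in catalogue:
        sig = signals[d.name]
        out[d.name] = range_of_movement(sig)
        if mode == "extended":
            for s, v in signal_statistics(sig).items():
                out[f"{d.name}_{s}"] = v
    return out


def build_feature_table(
    sequences: Iterable[PoseSequence],
    catalogue: Sequence[SignalDef] | None = None,
    mode: str = "rom",
    **signal_kwargs,
) -> FeatureTable:
    """Compute the features of every recording and assemble the table.

    Recordings in which any catalogue signal has no valid frame are
    excluded from the table and listed in ``excluded`` with the reason.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    catalogue = list(catalogue) if catalogue is not None else default_catalogue()
    sequences = list(sequences)
    if not sequences:
        raise InsufficientDataError("need at least one sequence")

    cols = feature_columns(catalogue, mode)
    rows = []
    excluded: list[tuple[str, str]] = []
    for seq in sequences:
        try:
            signals = compute_signals(seq, catalogue, **signal_kwargs)
            vec = feature_vector(signals, catalogue, mode)
        except EmptySignalError as exc:
            excluded.append((seq.recording_id, str(exc)))
            continue
        row = {"recording_id": seq.recording_id,
               "subject_id": seq.subject_id,
               "test_id": seq.test_id}
        row.update(vec)
        rows.append(row)

    frame = pd.DataFrame(rows, columns=["recording_id", "subject_id", "test_id", *cols])
    spec = {
        "catalogue": [[d.name, d.category, list(d.keypoints)] for d in catalogue],
        "mode": mode,
        "signal_kwargs": {k: str(v) for k, v in sorted(signal_kwargs.items())},
    }
    digest = hashlib.sha256(json.dumps(spec, sort_keys=True).encode()).hexdigest()
    return FeatureTable(frame=frame, excluded=excluded,
                        provenance={"spec": spec, "hash": digest})
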