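"""Synthetic BODY_25 cohorts for the two functional tests.

The generator emits skeleton clips that *look like* OpenPose output for a
Single Leg Squat Test or Step Down Test recording: a 1280x720 image, 30
fps, ~15 s, three squat repetitions on one stance limb, with Gaussian
keypoint jitter standing in for detector noise.  It is a signal-level
simulation, not a biomechanical model: the squat follows a raised-cosine
depth envelope and the stance leg is posed as a symmetric two-segment
linkage so that the 2D knee angle sweeps exactly from the standing angle
to the configured depth and back.

Six execution-error modes can be injected with controllable magnitude;
each one perturbs the kinematic signal family a physiotherapist would
watch for that error, and a magnitude of zero returns the input
unchanged.  Simulated raters with configurable sensitivity/specificity
turn the ground-truth error labels into a three-rater assessment table,
closing the loop for end-to-end testing of the agreement gate and the
classifier without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import RatingTable
from .errors import ConfigurationError
from .pose_io import N_KEYPOINTS, PoseSequence

IMAGE_SIZE = (1280, 720)

#: The six binary error parameters the classifier answers.
ERROR_MODES = (
    "loss_of_balance",
    "gross_arm_deviation",
    "forward_lean",
    "shallow_squat",
    "hip_drop",
    "tremor",
)

#: Default injection magnitudes — the "large" effect used for recovery
#: studies; units are per-mode (degrees for angular modes, pixels for
#: displacement modes).
DEFAULT_MAGNITUDES = {
    "loss_of_balance": 40.0,    # px lateral sway of the upper body
    "gross_arm_deviation": 60.0,  # px outward wrist displacement
    "forward_lean": 15.0,       # deg trunk rotation about the mid-hip
    "shallow_squat": 30.0,      # deg reduction of squat depth
    "hip_drop": 12.0,           # deg pelvis-line tilt
    "tremor": 8.0,              # px band-limited knee/ankle oscillation
}

# Keypoints rigidly attached to the trunk (everything above the hips plus
# the face): the set rotated by a forward lean and translated by a
# balance-loss sway.
_UPPER_BODY = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 15, 16, 17, 18])
_HIPS = np.array([9, 12])
_TREMOR_TARGETS = np.array([10, 11, 13, 14])  # both knees and ankles

_STANCE = {
    "right": {"hip": 9, "knee": 10, "ankle": 11, "foot": (22, 23, 24), "sign": -1.0},
    "left": {"hip": 12, "knee": 13, "ankle": 14, "foot": (19, 20, 21), "sign": 1.0},
}


@dataclass(frozen=True)
class ErrorSpec:
    """One injectable execution error: a mode and its magnitude."""

    mode: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in ERROR_MODES:
            raise ConfigurationError(
                f"unknown error mode {self.mode!r}; known: {ERROR_MODES}"
            )
        if self.magnitude < 0:
            raise ConfigurationError("magnitude must be >= 0")


@dataclass
class SubjectProfile:
    """Body geometry of one simulated subject.

    ``trunk_length`` (neck to mid-hip, pixels) is the scale unit; the
    stance template derives every other segment from it.  The default
    spread mirrors a healthy adult cohort (height 173.8 +/- 9.9 cm seen
    from 4 m, i.e. ~5.7% relative spread).
    """

    trunk_length: float = 150.0
    squat_depth_deg: float = 100.0
    pelvis_xy: tuple[float, float] = (640.0, 360.0)

    def __post_init__(self) -> None:
        if self.trunk_length <= 0:
            raise ConfigurationError("trunk_length must be positive")
        if not 30.0 < self.squat_depth_deg < 180.0:
            raise ConfigurationError("squat_depth_deg must lie in (30, 180)")


#: Standing template: keypoint offsets from the mid-hip in trunk units,
#: image convention (y positive downward).  Indices follow BODY_25.
_TEMPLATE = np.array([
    [0.00, -1.25],   # 0  Nose
    [0.00, -1.00],   # 1  Neck
    [-0.18, -0.95],  # 2  RShoulder
    [-0.22, -0.55],  # 3  RElbow
    [-0.24, -0.15],  # 4  RWrist
    [0.18, -0.95],   # 5  LShoulder
    [0.22, -0.55],   # 6  LElbow
    [0.24, -0.15],   # 7  LWrist
    [0.00, 0.00],    # 8  MidHip
    [-0.12, 0.02],   # 9  RHip
    [-0.13, 0.80],   # 10 RKnee
    [-0.14, 1.60],   # 11 RAnkle
    [0.12, 0.02],    # 12 LHip
    [0.13, 0.80],    # 13 LKnee
    [0.14, 1.60],    # 14 LAnkle
    [-0.04, -1.30],  # 15 REye
    [0.04, -1.30],   # 16 LEye
    [-0.08, -1.27],  # 17 REar
    [0.08, -1.27],   # 18 LEar
    [0.17, 1.68],    # 19 LBigToe
    [0.21, 1.67],    # 20 LSmallToe
    [0.13, 1.66],    # 21 LHeel
    [-0.17, 1.68],   # 22 RBigToe
    [-0.21, 1.67],   # 23 RSmallToe
    [-0.13, 1.66],   # 24 RHeel
])


@dataclass
class SimulationConfig:
    """Cohort-level knobs mirroring the emulated study protocol."""

    n_subjects: int = 46
    reps_per_limb: int = 3
    fps: float = 30.0
    duration_s: float = 15.0
    standing_knee_deg: float = 175.0
    squat_depth_deg: float = 100.0
    squat_depth_sd_deg: float = 3.0
    trunk_length_px: float = 150.0
    trunk_length_sd_px: float = 8.5
    step_height_ratio: float = 0.4  # 20 cm step in trunk units (~50 cm trunk)
    noise_sd: float = 1.0
    dropout_prob: float = 0.0
    error_prevalence: dict[str, float] = field(
        default_factory=lambda: {m: 0.1 for m in ERROR_MODES})
    error_magnitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAGNITUDES))
    rater_model: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.9, 0.95)] * 3)
    tests: tuple[str, ...] = ("SLST", "SDT")
    limb: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fps and duration_s must be positive")
        for m, p in self.error_prevalence.items():
            if m not in ERROR_MODES:
                raise ConfigurationError(f"unknown error mode {m!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {m} outside [0, 1]")
        if sum(self.error_prevalence.values()) > 1.0 + 1e-9:
            raise ConfigurationError("mode prevalences sum above 1")
        for se, sp in self.rater_model:
            if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
                raise ConfigurationError("rater sensitivity/specificity in [0, 1]")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob in [0, 1]")


def sample_profile(config: SimulationConfig, rng: np.random.Generator) -> SubjectProfile:
    trunk = max(40.0, rng.normal(config.trunk_length_px, config.trunk_length_sd_px))
    depth = float(np.clip(rng.normal(config.squat_depth_deg,
                                     config.squat_depth_sd_deg), 60.0, 160.0))
    return SubjectProfile(trunk_length=float(trunk), squat_depth_deg=depth)


# ---------------------------------------------------------------------------
# Base motion
# ---------------------------------------------------------------------------

def squat_envelope(n_frames: int, fps: float, reps: int) -> np.ndarray:
    """Raised-cosine depth envelope w(t) in [0, 1].

    The clip splits into ``reps`` equal slots; within each, the middle
    80% is one smooth descend-and-rise cycle, the rest upright standing.
    """
    t = np.arange(n_frames) / fps
    duration = n_frames / fps
    slot = duration / reps
    u = (t % slot) / slot
    w = np.zeros(n_frames)
    active = (u >= 0.1) & (u <= 0.9)
    phase = (u[active] - 0.1) / 0.8
    w[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return w


def generate_base_motion(
    test_id: str,
    profile: SubjectProfile,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    limb: str | None = None,
) -> PoseSequence:
    """One error-free recording of a test repetition sequence.

    The stance knee angle sweeps from the standing angle (default 175
    degrees) to the subject's squat depth and back once per repetition;
    the trunk stays vertical; every keypoint receives independent
    Gaussian jitter of ``noise_sd`` pixels.  Deterministic for a fixed
    generator state.
    """
    limb = limb or config.limb
    if limb not in _STANCE:
        raise ConfigurationError(f"stance limb must be 'left' or 'right', got {limb!r}")
    st = _STANCE[limb]
    T = profile.trunk_length
    n = int(round(config.duration_s * config.fps))

    tmpl = _TEMPLATE.copy()
    if test_id == "SLST":
        # free leg lifted: flexed knee, raised ankle and foot
        free = _STANCE["left" if limb == "right" else "right"]
        fsign = free["sign"]
        tmpl[free["knee"]] = [fsign * 0.20, 0.45]
        tmpl[free["ankle"]] = [fsign * 0.22, 0.90]
        for j, off in zip(free["foot"], ([0.03, 0.06], [0.07, 0.05], [-0.01, 0.04])):
            tmpl[j] = tmpl[free["ankle"]] + np.array([fsign * abs(off[0]), off[1]])
    elif test_id != "SDT":
        raise ConfigurationError(f"unknown test_id {test_id!r}")

    offsets = tmpl * T  # px offsets from mid-hip
    pelvis0 = np.array(profile.pelvis_xy)

    ankle = pelvis0 + offsets[st["ankle"]]
    if test_id == "SDT":
        ankle = ankle - np.array([0.0, config.step_height_ratio * T])  # on the step
    L1 = np.linalg.norm(offsets[st["hip"]] - offsets[st["knee"]])
    L2 = np.linalg.norm(offsets[st["knee"]] - offsets[st["ankle"]])

    w = squat_envelope(n, config.fps, config.reps_per_limb)
    theta = config.standing_knee_deg - (config.standing_knee_deg
                                        - profile.squat_depth_deg) * w
    beta = np.radians(180.0 - theta) / 2.0  # segment tilt from vertical
    sign = st["sign"]

    knee = np.empty((n, 2))
    knee[:, 0] = ankle[0] + sign * L2 * np.sin(beta)
    knee[:, 1] = ankle[1] - L2 * np.cos(beta)
    hip = np.empty((n, 2))
    hip[:, 0] = knee[:, 0] - sign * L1 * np.sin(beta)
    hip[:, 1] = knee[:, 1] - L1 * np.cos(beta)

    pelvis = hip - offsets[st["hip"]]  # mid-hip rides on the stance hip

    xy = pelvis[:, None, :] + offsets[None, :, :]
    xy[:, st["knee"]] = knee
    xy[:, st["ankle"]] = ankle
    for j in st["foot"]:
        xy[:, j] = ankle + (offsets[j] - offsets[st["ankle"]])

    xy += rng.normal(0.0, config.noise_sd, size=xy.shape)
    conf = rng.uniform(0.75, 0.99, size=(n, N_KEYPOINTS))
    missing = np.zeros((n, N_KEYPOINTS), dtype=bool)
    if config.dropout_prob > 0:
        drop = rng.random((n, N_KEYPOINTS)) < config.dropout_prob
        missing |= drop
        xy[drop] = 0.0
        conf[drop] = 0.0

    return PoseSequence(
        xy=xy, confidence=conf, missing=missing,
        frame_indices=np.arange(n), fps=config.fps,
        subject_id=subject_id, test_id=test_id, limb=limb,
    )


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------

def _depth_proxy(seq: PoseSequence) -> np.ndarray:
    """Squat-phase proxy in [0, 1] from the mid-hip vertical excursion."""
    y = seq.xy[:, 8, 1]
    span = y.max() - y.min()
    if span < 1e-9:
        return np.zeros(len(seq))
    return (y - y.min()) / span


def _rotate_about(xy: np.ndarray, indices: np.ndarray, center: np.ndarray,
                  angle_rad: np.ndarray) -> None:
    """In-place per-frame rotation of selected keypoints about a center."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rel = xy[:, indices, :] - center[:, None, :]
    xr = c[:, None] * rel[:, :, 0] - s[:, None] * rel[:, :, 1]
    yr = s[:, None] * rel[:, :, 0] + c[:, None] * rel[:, :, 1]
    xy[:, indices, 0] = center[:, None, 0] + xr
    xy[:, indices, 1] = center[:, None, 1] + yr


def _band_limited_noise(n: int, fps: float, band: tuple[float, float],
                        shape: tuple[int, ...],
                        rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise restricted to a frequency band, along axis 0."""
    white = rng.standard_normal((n, *shape))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n, 1.0 / fps)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=0)
    sd = out.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def inject_error(
    seq: PoseSequence,
    spec: ErrorSpec,
    rng: np.random.Generator | None = None,
) -> PoseSequence:
    """Apply one execution error to a clean recording.

    Effects by mode (magnitude ``m``):

    * ``forward_lean`` — the trunk (keypoints 0-8 and face) rotates about
      the mid-hip by up to ``m`` degrees, in phase with the squat depth;
    * ``hip_drop`` — the hip pair (9, 12) tilts about the mid-hip by up
      to ``m`` degrees with the squat depth;
    * ``gross_arm_deviation`` — both wrists (and half of each elbow)
      swing outward by up to ``m`` pixels with the squat depth;
    * ``loss_of_balance`` — a transient lateral sway: the upper body
      (0-8 and face) translates by ``m`` pixels under a Gaussian bump
      mid-clip while the feet stay planted;
    * ``shallow_squat`` — the stance-leg linkage is re-posed so the knee
      angle at peak depth is ``m`` degrees shallower;
    * ``tremor`` — band-limited 8-12 Hz oscillation of standard
      deviation ``m`` pixels on both knees and ankles (physiological
      tremor band, below the 15 Hz Nyquist limit of 30 fps capture).

    Magnitude zero returns an identical copy.  Each targeted feature
    responds monotonically to the magnitude.
    """
    if spec.magnitude == 0.0:
        return seq.copy()
    rng = rng if rng is not None else np.random.default_rng(0)
    out = seq.copy()
    xy = out.xy
    n = len(seq)
    w = _depth_proxy(seq)
    midhip = seq.xy[:, 8, :]

    if spec.mode == "forward_lean":
        _rotate_about(xy, _UPPER_BODY, midhip, np.radians(spec.magnitude) * w)
    elif spec.mode == "hip_drop":
        _rotate_about(xy, _HIPS, midhip, np.radians(spec.magnitude) * w)
    elif spec.mode == "gross_arm_deviation":
        # outward = away from the body midline at the mid-hip
        for wrist, elbow in ((4, 3), (7, 6)):
            side = np.sign(seq.xy[:, wrist, 0] - midhip[:, 0])
            side[side == 0] = 1.0
            xy[:, wrist, 0] += side * spec.magnitude * w
            xy[:, elbow, 0] += side * 0.5 * spec.magnitude * w
    elif spec.mode == "loss_of_balance":
        t = seq.frame_indices / seq.fps
        center = 0.55 * (t[-1] if len(t) else 0.0)
        bump = np.exp(-0.5 * ((t - center) / 0.6) ** 2)
        xy[:, _UPPER_BODY, 0] += (spec.magnitude * bump)[:, None]
    elif spec.mode == "shallow_squat":
        _reduce_squat_depth(out, spec.magnitude, w)
    elif spec.mode == "tremor":
        noise = _band_limited_noise(n, seq.fps, (8.0, 12.0),
                                    (_TREMOR_TARGETS.size, 2), rng)
        xy[:, _TREMOR_TARGETS, :] += spec.magnitude * noise
    return out


def _reduce_squat_depth(seq: PoseSequence, magnitude_deg: float,
                        w: np.ndarray) -> None:
    """Re-pose the stance leg so peak knee flexion shrinks by ``magnitude_deg``.

    The stance shank and thigh tilts are recovered per frame from the
    linkage geometry, reduced symmetrically, and the resulting pelvis
    displacement is applied to everything not anchored to the stance
    foot.
    """
    limb = seq.limb if seq.limb in _STANCE else "right"
    st = _STANCE[limb]
    sign = st["sign"]
    xy = seq.xy
    A = xy[:, st["ankle"], :]
    K = xy[:, st["knee"], :]
    H = xy[:, st["hip"], :]

    L2 = np.linalg.norm(K - A, axis=1)
    L1 = np.linalg.norm(H - K, axis=1)
    beta_shank = np.arctan2(sign * (K[:, 0] - A[:, 0]), A[:, 1] - K[:, 1])
    beta_thigh = np.arctan2(-sign * (H[:, 0] - K[:, 0]), K[:, 1] - H[:, 1])
    delta = 0.5 * np.radians(magnitude_deg) * w
    b2 = np.maximum(beta_shank - delta, 0.0)
    b1 = np.maximum(beta_thigh - delta, 0.0)

    K_new = np.column_stack([A[:, 0] + sign * L2 * np.sin(b2),
                             A[:, 1] - L2 * np.cos(b2)])
    H_new = np.column_stack([K_new[:, 0] - sign * L1 * np.sin(b1),
                             K_new[:, 1] - L1 * np.cos(b1)])
    shift = H_new - H

    anchored = {st["knee"], st["ankle"], *st["foot"]}
    moving = np.array([j for j in range(N_KEYPOINTS) if j not in anchored])
    xy[:, moving, :] += shift[:, None, :]
    xy[:, st["knee"], :] = K_new


# ---------------------------------------------------------------------------
# Raters and cohorts
# ---------------------------------------------------------------------------

def simulate_raters(
    true_labels: pd.DataFrame,
    rater_model: Sequence[tuple[float, float]],
    rng: np.random.Generator,
) -> RatingTable:
    """Imperfect raters around ground truth.

    ``true_labels``: subjects (index) x parameters (columns), binary.
    Each rater with (sensitivity, specificity) marks a truly faulty cell
    faulty with probability ``sensitivity`` and a truly clean cell clean
    with probability ``specificity``, independently per cell.  Perfect
    raters (1, 1) reproduce the truth exactly.
    """
    truth = true_labels.to_numpy(dtype=int)
    s, p = truth.shape
    ratings = np.empty((s, len(rater_model), p), dtype=int)
    for r, (se, sp) in enumerate(rater_model):
        u = rng.random((s, p))
        ratings[:, r, :] = np.where(truth == 1, (u < se), (u >= sp)).astype(int)
    return RatingTable(
        ratings=ratings,
        subjects=[str(i) for i in true_labels.index],
        raters=[f"rater_{r + 1}" for r in range(len(rater_model))],
        parameters=[str(c) for c in true_labels.columns],
    )


@dataclass
class SimulatedCohort:
    """A full synthetic study: recordings, ground truth and ratings."""

    sequences: list[PoseSequence]
    true_labels: pd.DataFrame  # subject_id, test_id, one column per mode
    ratings: dict[str, RatingTable]  # per test
    config: SimulationConfig

    def sequences_for(self, test_id: str) -> list[PoseSequence]:
        return [s for s in self.sequences if s.test_id == test_id]

    def labels_for(self, test_id: str) -> pd.DataFrame:
        sub = self.true_labels[self.true_labels["test_id"] == test_id]
        return sub.set_index("subject_id")[list(ERROR_MODES)]


def generate_dataset(config: SimulationConfig) -> SimulatedCohort:
    """Generate a reproducible cohort under the configured protocol.

    Per test, every subject contributes one recording; at most one error
    mode per recording is drawn from ``error_prevalence`` (the remainder
    is error-free execution), injected at the mode's configured
    magnitude.  Simulated raters then assess the six parameters.
    """
    rng = np.random.default_rng(config.seed)
    subjects = [f"S{i + 1:03d}" for i in range(config.n_subjects)]
    profiles = [sample_profile(config, rng) for _ in subjects]

    modes = list(ERROR_MODES)
    p_modes = np.array([config.error_prevalence.get(m, 0.0) for m in modes])
    p_choice = np.append(p_modes, 1.0 - p_modes.sum())
    choices = modes + [None]

    sequences: list[PoseSequence] = []
    label_rows = []
    ratings: dict[str, RatingTable] = {}
    for test in config.tests:
        truth = np.zeros((config.n_subjects, len(modes)), dtype=int)
        for i, (sid, profile) in enumerate(zip(subjects, profiles)):
            seq = generate_base_motion(test, profile, config, rng,
                                       subject_id=sid)
            drawn = choices[int(rng.choice(len(choices), p=p_choice))]
            if drawn is not None:
                mag = config.error_magnitudes.get(drawn, DEFAULT_MAGNITUDES[drawn])
                seq = inject_error(seq, ErrorSpec(drawn, mag), rng)
                truth[i, modes.index(drawn)] = 1
            sequences.append(seq)
            label_rows.append({"subject_id": sid, "test_id": test,
                               **{m: int(truth[i, j]) for j, m in enumerate(modes)}})
        truth_df = pd.DataFrame(truth, index=subjects, columns=modes)
        ratings[test] = simulate_raters(truth_df, config.rater_model, rng)

    return SimulatedCohort(
        sequences=sequences,
        true_labels=pd.DataFrame(label_rows),
        ratings=ratings,
        config=config,
    )
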