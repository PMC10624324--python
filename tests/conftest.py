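import numpy as np
import pytest

from movequal.simulate import SimulationConfig, generate_dataset


def make_person(xy_conf):
    """Flatten a 25 x (x, y, c) array into an OpenPose person record."""
    flat = [float(v) for kp in xy_conf for v in kp]
    return {"person_id": [-1], "pose_keypoints_2d": flat}


def make_frame_doc(*people):
    return {"version": 1.3, "people": list(people)}


def grid_skeleton(offset=0.0, conf=0.9):
    """25 well-spread keypoints: a deterministic synthetic pose."""
    return [(100.0 + 40.0 * (k % 5) + offset, 100.0 + 40.0 * (k // 5), conf)
            for k in range(25)]


@pytest.fixture
def frame_doc():
    return make_frame_doc(make_person(grid_skeleton()))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """16 subjects, one test, two error modes, perfect raters; 5 s clips."""
    cfg = SimulationConfig(
        n_subjects=16,
        duration_s=5.0,
        tests=("SLST",),
        error_prevalence={"forward_lean": 0.4, "tremor": 0.3},
        rater_model=[(1.0, 1.0)] * 3,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_sequence():
    """One noise-free error-free SLST recording at protocol scale."""
    from movequal.simulate import SubjectProfile, generate_base_motion

    cfg = SimulationConfig(noise_sd=0.0, seed=1)
    rng = np.random.default_rng(1)
    return generate_base_motion("SLST", SubjectProfile(), cfg, rng,
                                subject_id="clean")
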