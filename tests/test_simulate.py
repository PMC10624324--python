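import numpy as np
import pandas as pd
import pytest

from movequal import kinematics as km
from movequal import simulate as sim
from movequal.errors import ConfigurationError
from movequal.features import build_feature_table


def base_seq(noise_sd=1.0, test_id="SLST", seed=2, duration_s=15.0):
    cfg = sim.SimulationConfig(noise_sd=noise_sd, duration_s=duration_s, seed=seed)
    rng = np.random.default_rng(seed)
    return sim.generate_base_motion(test_id, sim.SubjectProfile(), cfg, rng)


def signal(seq, name):
    defs = {d.name: d for d in km.default_catalogue()}
    return km.compute_signal(seq, defs[name])


class TestBaseMotion:
    def test_protocol_defaults(self):
        seq = base_seq()
        assert len(seq) == 450  # 15 s x 30 fps
        assert seq.xy.shape == (450, 25, 2)
        assert not seq.missing.any()

    def test_noiseless_trunk_is_constant(self):
        seq = base_seq(noise_sd=0.0)
        spine = signal(seq, "Spine")
        assert np.ptp(spine.valid_values) <= 1e-6

    def test_knee_sweep_reaches_configured_depth(self):
        seq = base_seq()
        knee = signal(seq, "RHipRKneeRAnkle")
        assert knee.valid_values.min() == pytest.approx(100.0, abs=2.0)

    def test_three_repetitions(self):
        seq = base_seq(noise_sd=0.0)
        knee = signal(seq, "RHipRKneeRAnkle").values
        deep = knee < 120.0
        # count contiguous deep-flexion episodes
        episodes = int(np.sum(np.diff(deep.astype(int)) == 1) + deep[0])
        assert episodes == 3

    def test_sdt_stance_on_step(self):
        slst = base_seq(noise_sd=0.0, test_id="SLST")
        sdt = base_seq(noise_sd=0.0, test_id="SDT")
        # stance ankle sits one step height (0.4 trunk units) higher on SDT
        assert slst.xy[0, 11, 1] - sdt.xy[0, 11, 1] == pytest.approx(60.0, abs=1.0)

    def test_frames_fit_image(self):
        seq = base_seq()
        assert (seq.xy[:, :, 0] > 0).all() and (seq.xy[:, :, 0] < 1280).all()
        assert (seq.xy[:, :, 1] > 0).all() and (seq.xy[:, :, 1] < 720).all()

    def test_unknown_test_rejected(self):
        with pytest.raises(ConfigurationError):
            base_seq(test_id="NOPE")


class TestInjectError:
    def test_zero_magnitude_identity(self):
        seq = base_seq(duration_s=3.0)
        for mode in sim.ERROR_MODES:
            out = sim.inject_error(seq, sim.ErrorSpec(mode, 0.0))
            assert np.array_equal(out.xy, seq.xy), mode

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            sim.ErrorSpec("jazz_hands", 1.0)

    def test_forward_lean_raises_spine_rom_by_its_magnitude(self):
        seq = base_seq(noise_sd=0.0)
        lean = sim.inject_error(seq, sim.ErrorSpec("forward_lean", 15.0))
        clean_rom = np.ptp(signal(seq, "Spine").valid_values)
        lean_rom = np.ptp(signal(lean, "Spine").valid_values)
        assert lean_rom - clean_rom == pytest.approx(15.0, abs=0.5)

    def test_hip_drop_tilts_hip_line(self):
        seq = base_seq(noise_sd=0.0)
        drop = sim.inject_error(seq, sim.ErrorSpec("hip_drop", 12.0))
        assert np.ptp(signal(drop, "Hips").valid_values) \
            - np.ptp(signal(seq, "Hips").valid_values) == pytest.approx(12.0, abs=0.5)

    def test_tremor_strictly_inflates_knee_signal_jitter_power(self):
        # the added band-limited power shows in the first-difference
        # variance, which isolates frame-to-frame motion from the sweep
        seq = base_seq()
        shaky = sim.inject_error(seq, sim.ErrorSpec("tremor", 8.0),
                                 np.random.default_rng(5))
        assert np.diff(signal(shaky, "RHipRKneeRAnkle").valid_values).var() \
            > np.diff(signal(seq, "RHipRKneeRAnkle").valid_values).var()

    def test_shallow_squat_reduces_depth_by_magnitude(self):
        seq = base_seq(noise_sd=0.0)
        shallow = sim.inject_error(seq, sim.ErrorSpec("shallow_squat", 30.0))
        clean_min = signal(seq, "RHipRKneeRAnkle").valid_values.min()
        shallow_min = signal(shallow, "RHipRKneeRAnkle").valid_values.min()
        assert shallow_min - clean_min == pytest.approx(30.0, abs=1.0)

    def test_loss_of_balance_spares_orientations(self):
        seq = base_seq(noise_sd=0.0)
        sway = sim.inject_error(seq, sim.ErrorSpec("loss_of_balance", 40.0))
        # the sway translates the whole trunk: spine orientation unmoved ...
        np.testing.assert_allclose(signal(sway, "Spine").values,
                                   signal(seq, "Spine").values, atol=1e-9)
        # ... while the planted legs make the hip angles move
        assert np.ptp(signal(sway, "MidHipLHipLKnee").valid_values) \
            > np.ptp(signal(seq, "MidHipLHipLKnee").valid_values) + 5.0

    @pytest.mark.parametrize("mode", sim.ERROR_MODES)
    def test_targeted_rom_monotone_in_magnitude(self, mode):
        target = {"loss_of_balance": "MidHipLHipLKnee",
                  "gross_arm_deviation": "RWristMidHip",
                  "forward_lean": "Spine",
                  "shallow_squat": "RHipRKneeRAnkle",
                  "hip_drop": "Hips",
                  "tremor": "RHipRKneeRAnkle"}[mode]
        seq = base_seq(noise_sd=0.0)
        full = sim.DEFAULT_MAGNITUDES[mode]
        roms = []
        for mag in (0.0, 0.5 * full, full):
            out = sim.inject_error(seq, sim.ErrorSpec(mode, mag),
                                   np.random.default_rng(4))
            roms.append(np.ptp(signal(out, target).valid_values))
        if mode == "shallow_squat":  # clipping the envelope shrinks the sweep
            assert roms[0] > roms[1] > roms[2]
        else:
            assert roms[0] < roms[1] < roms[2]


class TestRaters:
    def test_perfect_raters_reproduce_truth(self, rng):
        truth = pd.DataFrame(rng.integers(0, 2, size=(30, 4)),
                             index=[f"S{i}" for i in range(30)],
                             columns=list("abcd"))
        table = sim.simulate_raters(truth, [(1.0, 1.0)] * 3, rng)
        for r in range(3):
            assert np.array_equal(table.ratings[:, r, :], truth.to_numpy())

    def test_perfect_raters_unit_kappa(self, rng):
        from movequal.agreement import build_report
        truth = pd.DataFrame({"p": rng.integers(0, 2, size=40)},
                             index=[f"S{i}" for i in range(40)])
        table = sim.simulate_raters(truth, [(1.0, 1.0)] * 3, rng)
        assert (build_report(table).frame["kappa"] == 1.0).all()

    def test_coin_flip_raters_near_zero_kappa(self):
        from movequal.agreement import fleiss_kappa
        rng = np.random.default_rng(8)
        truth = pd.DataFrame({"p": rng.integers(0, 2, size=1000)})
        table = sim.simulate_raters(truth, [(0.5, 0.5)] * 3, rng)
        assert abs(fleiss_kappa(table.for_parameter("p"))) < 0.05

    def test_kappa_matches_enumeration_expectation(self):
        """Raters at (0.9, 0.9) on balanced truth: the expected kappa is
        computed analytically by enumerating agreement probabilities."""
        se, sp, prev = 0.9, 0.9, 0.5
        q = {1: se, 0: 1 - sp}  # P(rate faulty | truth)
        p_bar = sum(p * (q[t] ** 2 + (1 - q[t]) ** 2)
                    for t, p in ((1, prev), (0, 1 - prev)))
        p1 = prev * q[1] + (1 - prev) * q[0]
        p_e = p1 ** 2 + (1 - p1) ** 2
        expected = (p_bar - p_e) / (1 - p_e)

        from movequal.agreement import fleiss_kappa
        rng = np.random.default_rng(3)
        truth = pd.DataFrame({"p": np.repeat([0, 1], 250)})
        table = sim.simulate_raters(truth, [(se, sp)] * 3, rng)
        assert fleiss_kappa(table.for_parameter("p")) \
            == pytest.approx(expected, abs=0.05)


class TestGenerateDataset:
    def test_reproducible_from_seed(self):
        cfg = sim.SimulationConfig(n_subjects=5, duration_s=3.0, seed=7)
        a, b = sim.generate_dataset(cfg), sim.generate_dataset(cfg)
        for s1, s2 in zip(a.sequences, b.sequences):
            assert np.array_equal(s1.xy, s2.xy)
        assert a.true_labels.equals(b.true_labels)
        for t in a.ratings:
            assert np.array_equal(a.ratings[t].ratings, b.ratings[t].ratings)

    def test_zero_prevalence_all_clean(self):
        cfg = sim.SimulationConfig(
            n_subjects=6, duration_s=2.0, seed=1,
            error_prevalence={m: 0.0 for m in sim.ERROR_MODES})
        cohort = sim.generate_dataset(cfg)
        assert not cohort.true_labels[list(sim.ERROR_MODES)].to_numpy().any()

    def test_prevalence_within_binomial_bound(self):
        cfg = sim.SimulationConfig(
            n_subjects=200, duration_s=2.0, tests=("SLST",), seed=17,
            error_prevalence={"forward_lean": 0.25})
        cohort = sim.generate_dataset(cfg)
        frac = cohort.labels_for("SLST")["forward_lean"].mean()
        assert frac == pytest.approx(0.25, abs=0.07)

    def test_every_frame_passes_pose_validation(self, small_cohort):
        for seq in small_cohort.sequences[:4]:
            assert not seq.missing.any()
            assert ((seq.confidence >= 0) & (seq.confidence <= 1)).all()

    def test_default_magnitudes_separate_by_three_pooled_sd(self):
        """Each mode's default magnitude shifts its target feature by at
        least 3 pooled standard deviations in a protocol-scale cohort."""
        target = {"loss_of_balance": "MidHipLRSmallToe",
                  "gross_arm_deviation": "RWristMidHip",
                  "forward_lean": "Spine",
                  "shallow_squat": "RHipRKneeRAnkle",
                  "hip_drop": "Hips",
                  "tremor": "RHipRKneeRAnkle"}
        for mode in sim.ERROR_MODES:
            cfg = sim.SimulationConfig(n_subjects=60, tests=("SLST",), seed=13,
                                       error_prevalence={mode: 0.5})
            cohort = sim.generate_dataset(cfg)
            table = build_feature_table(cohort.sequences)
            y = cohort.labels_for("SLST")[mode].to_numpy()
            f = table.frame[target[mode]].to_numpy()
            a, b = f[y == 0], f[y == 1]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            shift = abs(b.mean() - a.mean()) / pooled
            assert shift >= 3.0, f"{mode}: {shift:.2f} pooled SD"
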