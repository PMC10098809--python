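import numpy as np
import pytest

from i2spair.gait_sim import SimConfig, generate_bout
from i2spair.imu_signals import ImuRecording, mirror_recording
from i2spair.side_id import (
    SideFeatures,
    SideIdError,
    apply_calibration,
    assign_limb_side,
    classify_foot_side,
    detect_foot_flat,
    foot_side_features,
    functional_calibration,
    train_foot_side_model,
)

from conftest import random_rotation


def _norm_rec(gyr_norm_profile, fs=200.0):
    """Recording whose |Gyr| equals the given non-negative profile."""
    n = len(gyr_norm_profile)
    gyr = np.zeros((n, 3))
    gyr[:, 0] = gyr_norm_profile
    acc = np.zeros((n, 3))
    acc[:, 1] = 1.0
    return ImuRecording("n", fs, gyr, acc)


def _clean_foot_bout(side="right", stride=1.0, cycles=6, seed=8, rotate=False):
    cfg = SimConfig(
        seed=seed,
        orientation_randomization=rotate,
        gyr_noise_sd=0.0 if not rotate else 1.0,
        acc_noise_sd=0.0 if not rotate else 0.02,
        cycle_variability_sd=0.0,
    )
    bout = generate_bout(cfg, 0, stride_time=stride, n_cycles=cycles)
    return bout, bout.recordings[f"foot_{side}"]


class TestDetectFootFlat:
    def test_all_quiet_is_one_interval_covering_the_bout(self):
        rec = _norm_rec(np.zeros(400))
        flats = detect_foot_flat(rec, stride_time=1.0)
        assert flats.intervals == [(0, 400)]

    def test_square_wave_yields_one_interval_per_cycle(self):
        fs = 200.0
        cycle = np.concatenate([np.zeros(60), np.full(140, 200.0)])  # 0.3 s + 0.7 s
        rec = _norm_rec(np.tile(cycle, 4), fs=fs)
        flats = detect_foot_flat(rec, stride_time=1.0)
        assert len(flats.intervals) == 4
        for s, e in flats.intervals:
            assert (e - s) == 60

    def test_run_shorter_than_fifteen_percent_rejected(self):
        fs = 200.0
        cycle = np.concatenate([np.zeros(20), np.full(180, 200.0)])  # 0.10 s quiet
        rec = _norm_rec(np.tile(cycle, 4), fs=fs)
        with pytest.raises(SideIdError, match="no foot flat"):
            detect_foot_flat(rec, stride_time=1.0)


class TestFunctionalCalibration:
    def test_anatomical_signal_is_a_fixed_point(self):
        # a foot signal already in the anatomical frame with the correct
        # hindfoot-lift sign calibrates to ~identity (up to a small
        # rotation about Y from the finite PCA sample)
        _, rec = _clean_foot_bout()
        flats = detect_foot_flat(rec, 1.0)
        cal = functional_calibration(rec, flats)
        assert np.allclose(cal.rotation @ cal.rotation.T, np.eye(3), atol=1e-9)
        cal_rec = apply_calibration(rec, cal)
        assert np.allclose(cal_rec.gyr[:, 2], rec.gyr[:, 2], atol=1e-6 + 0.05 * np.abs(rec.gyr[:, 2]).max())
        # Y axis must map exactly to itself (gravity was already on Y)
        assert cal.rotation[1, 1] == pytest.approx(1.0, abs=1e-6)

    def test_round_trip_recovers_pre_rotation_signal(self):
        bout, rec = _clean_foot_bout()
        rng = np.random.default_rng(11)
        flats = detect_foot_flat(rec, 1.0)
        for _ in range(5):
            R = random_rotation(rng)
            rotated = rec.rotated(R)
            cal = functional_calibration(rotated, detect_foot_flat(rotated, 1.0))
            recovered = apply_calibration(rotated, cal)
            # the sagittal (plantar/dorsiflexion) trace must match the
            # anatomical original; residual Y-rotation leaves Gyr_z intact
            err = np.abs(recovered.gyr[:, 2] - rec.gyr[:, 2]).max()
            assert err < 0.05 * np.abs(rec.gyr[:, 2]).max()

    def test_both_feet_share_the_plantar_flexion_sign(self):
        # after calibration, push-off plantar flexion is negative Gyr_z on
        # both feet — the side information lives in the other channels
        for side in ("right", "left"):
            _, rec = _clean_foot_bout(side=side)
            flats = detect_foot_flat(rec, 1.0)
            cal = functional_calibration(rec, flats)
            cal_rec = apply_calibration(rec, cal)
            feats = foot_side_features(cal_rec, flats)
            gz_at_peaks = cal_rec.gyr[:, 2]
            assert gz_at_peaks.min() < 0
            # the first post-flat peak has negative pitch velocity
            from i2spair.side_id import _post_flat_peaks

            peaks = _post_flat_peaks(cal_rec.gyr_norm(), flats, cal_rec.fs)
            assert np.median(gz_at_peaks[peaks]) < 0

    def test_degenerate_pca_rejected(self):
        # a circular rotation has two exactly equal principal axes: no
        # dominant sagittal axis exists and calibration must refuse
        n, fs = 800, 200.0
        t = np.arange(700) / fs
        gyr = np.zeros((n, 3))
        gyr[100:, 0] = 80 * np.cos(2 * np.pi * 2 * t)
        gyr[100:, 1] = 80 * np.sin(2 * np.pi * 2 * t)
        acc = np.zeros((n, 3))
        acc[:, 1] = 1.0
        rec = ImuRecording("circ", fs, gyr, acc)
        flats = detect_foot_flat(rec, 1.0)
        with pytest.raises(SideIdError, match="degenerate"):
            functional_calibration(rec, flats)


class TestFootSideFeatures:
    def test_identity_extraction_at_constructed_peak(self):
        fs = 200.0
        n = 600
        gyr = np.zeros((n, 3))
        acc = np.zeros((n, 3))
        acc[:, 1] = 1.0
        # quiet for 0.5 s (foot flat), then one clean peak at sample 150
        bump = 200.0 * np.exp(-0.5 * ((np.arange(n) - 150) / 8.0) ** 2)
        gyr[:, 2] = -bump
        gyr[:, 0] = -30.0 / 200.0 * bump
        gyr[:, 1] = 40.0 / 200.0 * bump
        acc[:, 2] = 0.2 / 200.0 * bump
        rec = ImuRecording("one", fs, gyr, acc)
        flats = detect_foot_flat(rec, stride_time=0.6)
        feats = foot_side_features(rec, flats)
        assert feats.gyr_x_at_peak == pytest.approx(-30.0, rel=1e-6)
        assert feats.gyr_y_at_peak == pytest.approx(40.0, rel=1e-6)
        assert feats.acc_z_at_peak == pytest.approx(0.2, rel=1e-6)

    def test_mirroring_flips_all_three_features(self):
        _, rec = _clean_foot_bout(side="right")
        flats = detect_foot_flat(rec, 1.0)
        cal = functional_calibration(rec, flats)
        feats = foot_side_features(apply_calibration(rec, cal), flats)

        mirrored = mirror_recording(rec)
        mflats = detect_foot_flat(mirrored, 1.0)
        mcal = functional_calibration(mirrored, mflats)
        mfeats = foot_side_features(apply_calibration(mirrored, mcal), mflats)

        assert np.sign(mfeats.gyr_x_at_peak) == -np.sign(feats.gyr_x_at_peak)
        assert np.sign(mfeats.gyr_y_at_peak) == -np.sign(feats.gyr_y_at_peak)
        assert np.sign(mfeats.acc_z_at_peak) == -np.sign(feats.acc_z_at_peak)

    def test_right_foot_push_off_signs(self):
        # internal rotation positive on the right at the push-off peak
        _, rec = _clean_foot_bout(side="right")
        flats = detect_foot_flat(rec, 1.0)
        cal = functional_calibration(rec, flats)
        feats = foot_side_features(apply_calibration(rec, cal), flats)
        assert feats.gyr_y_at_peak > 0
        assert feats.gyr_x_at_peak > 0
        assert feats.acc_z_at_peak > 0


class TestClassifyFootSide:
    def test_untrained_model_rejected(self):
        with pytest.raises(SideIdError, match="untrained"):
            classify_foot_side(SideFeatures(1.0, 1.0, 0.1), None)

    def test_trained_tree_separates_sides_and_mirror_flips(self):
        rng = np.random.default_rng(6)
        rights = np.column_stack([
            rng.normal(25, 5, 40), rng.normal(90, 15, 40), rng.normal(0.2, 0.05, 40)
        ])
        feats = np.vstack([rights, -rights])
        sides = ["right"] * 40 + ["left"] * 40
        model = train_foot_side_model(feats, sides)
        probe = SideFeatures(20.0, 80.0, 0.15)
        assert classify_foot_side(probe, model) == "right"
        mirrored = SideFeatures(-20.0, -80.0, -0.15)
        assert classify_foot_side(mirrored, model) == "left"


class TestAssignLimbSide:
    def _pair(self, quiet_level, busy_level, n=800):
        quiet = _norm_rec(np.full(n, quiet_level))
        busy = _norm_rec(np.full(n, busy_level))
        return quiet, busy

    def _foot(self, n=800):
        profile = np.tile(np.concatenate([np.zeros(60), np.full(140, 300.0)]), n // 200)
        return _norm_rec(profile)

    def test_smaller_mean_gets_the_foot_side(self):
        quiet, busy = self._pair(12.0, 140.0)
        out = assign_limb_side({"A": quiet, "B": busy}, self._foot(), "right", 1.0)
        assert out == {"A": "right", "B": "left"}

    def test_swapped_inputs_swap_the_output(self):
        quiet, busy = self._pair(12.0, 140.0)
        out = assign_limb_side({"B": busy, "A": quiet}, self._foot(), "right", 1.0)
        assert out == {"A": "right", "B": "left"}

    def test_ambiguous_means_rejected(self):
        a, b = self._pair(100.0, 102.0)
        with pytest.raises(SideIdError, match="ambiguous"):
            assign_limb_side({"A": a, "B": b}, self._foot(), "left", 1.0)

    def test_exactly_two_members_required(self):
        (quiet,) = (self._pair(10.0, 100.0)[0],)
        with pytest.raises(SideIdError, match="two pair members"):
            assign_limb_side({"A": quiet}, self._foot(), "left", 1.0)

    def test_simulated_pairs_assigned_correctly(self):
        cfg = SimConfig(seed=13)
        for b in range(4):
            bout = generate_bout(cfg, 1, bout_index=b)
            T = bout.true_stride_time
            for seg in ("shank", "thigh"):
                out = assign_limb_side(
                    {f"{seg}_right": bout.recordings[f"{seg}_right"],
                     f"{seg}_left": bout.recordings[f"{seg}_left"]},
                    bout.recordings["foot_left"], "left", T,
                )
                assert out[f"{seg}_right"] == "right"
                assert out[f"{seg}_left"] == "left"
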