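import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from i2spair.features import (
    DEFAULT_SEGMENT_FEATURES,
    FEATURE_NAMES,
    FeatureError,
    FeatureVector,
    ZScoreParams,
    apply_zscore,
    count_zero_crossings,
    extract_features,
    features_to_frame,
    fit_zscore,
    scale_by_stride,
)
from i2spair.imu_signals import ImuRecording, derive_channels, lowpass_filter
from i2spair.gait_sim import SimConfig, generate_bout

from conftest import random_rotation


def _const_rec(gyr_val=50.0, n=400, fs=100.0):
    gyr = np.zeros((n, 3))
    gyr[:, 0] = gyr_val
    acc = np.zeros((n, 3))
    acc[:, 1] = 1.0
    return ImuRecording("c", fs, gyr, acc)


class TestScaleByStride:
    def test_unit_stride_is_identity(self):
        der = derive_channels(_const_rec())
        scaled = scale_by_stride(der, 1.0)
        assert np.allclose(scaled.gyr_norm, der.gyr_norm)

    def test_amplitude_multiplied_by_stride(self):
        der = derive_channels(_const_rec(gyr_val=10.0))
        scaled = scale_by_stride(der, 1.7)
        assert np.allclose(scaled.gyr_norm, 17.0)

    def test_non_positive_stride_rejected(self):
        der = derive_channels(_const_rec())
        with pytest.raises(FeatureError):
            scale_by_stride(der, 0.0)


class TestCatalog:
    def test_fifty_one_features(self):
        assert len(FEATURE_NAMES) == 51
        assert set(DEFAULT_SEGMENT_FEATURES) <= set(FEATURE_NAMES)

    def test_constant_signal_degenerate_statistics(self):
        fv = extract_features(_const_rec(gyr_val=50.0), stride_time=1.0)
        v = fv.values
        assert v["gyr_norm_min"] == v["gyr_norm_max"] == pytest.approx(50.0)
        assert v["gyr_norm_mean"] == v["gyr_norm_median"] == pytest.approx(50.0)
        assert v["gyr_norm_std"] == v["gyr_norm_iqr"] == v["gyr_norm_mad"] == 0.0
        assert v["gyr_norm_deriv_n_zero_crossings"] == 0.0

    def test_standing_still_is_fully_motionless(self):
        fv = extract_features(_const_rec(gyr_val=0.0), stride_time=1.0)
        assert fv.values["motionless_pct"] == 1.0

    def test_walking_foot_motionless_fraction_matches_flat(self):
        bout = generate_bout(
            SimConfig(seed=4, orientation_randomization=False, gyr_noise_sd=0.0,
                      acc_noise_sd=0.0, cycle_variability_sd=0.0),
            0, stride_time=1.0, n_cycles=6,
        )
        fv = extract_features(bout.recordings["foot_right"], 1.0)
        assert 0.1 < fv.values["motionless_pct"] < 0.45

    def test_bout_shorter_than_one_stride_rejected(self):
        with pytest.raises(FeatureError, match="shorter than one stride"):
            extract_features(_const_rec(n=50, fs=100.0), stride_time=1.0)

    def test_window_count_is_floor_of_duration_over_stride(self):
        fv = extract_features(_const_rec(n=950, fs=100.0), stride_time=3.0)
        assert fv.window_count == 3


class TestStatisticOracle:
    def test_each_statistic_matches_independent_formulas(self):
        # one full window of a reproducible random signal, each statistic
        # recomputed from first principles (sorted-order percentiles with
        # linear interpolation, raw moment ratios)
        rng = np.random.default_rng(42)
        n, fs = 200, 100.0
        gyr = np.abs(rng.normal(50, 20, size=(n, 3)))
        acc = rng.normal(0, 0.3, size=(n, 3)) + [0, 1, 0]
        rec = ImuRecording("o", fs, gyr, acc)
        T = n / fs
        fv = extract_features(rec, stride_time=T)
        x = np.linalg.norm(gyr, axis=1) * T  # scaled |Gyr| of the window

        def pct(q):
            s = np.sort(x)
            pos = q / 100 * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        m = x.sum() / len(x)
        d = x - m
        m2, m3, m4 = (d**2).mean(), (d**3).mean(), (d**4).mean()
        expected = {
            "gyr_norm_min": x.min(),
            "gyr_norm_max": x.max(),
            "gyr_norm_iqr": pct(75) - pct(25),
            "gyr_norm_p10": pct(10),
            "gyr_norm_p90": pct(90),
            "gyr_norm_mean": m,
            "gyr_norm_median": pct(50),
            "gyr_norm_kurtosis": m4 / m2**2,
            "gyr_norm_skewness": m3 / m2**1.5,
            "gyr_norm_std": np.sqrt((d**2).sum() / (len(x) - 1)),
            "gyr_norm_mad": np.abs(d).mean(),
        }
        for name, want in expected.items():
            assert fv.values[name] == pytest.approx(want, rel=1e-9), name


class TestZeroCrossings:
    @pytest.mark.parametrize(
        "x, want",
        [
            ([1, -1, 1, -1], 3),
            ([1, 2, 3], 0),
            ([1, 0, -1], 1),  # zero joins the following sign
            ([1, 0, 1], 0),
            ([-1, 0, 0, 2], 1),
            ([0, 0, 0], 0),
        ],
    )
    def test_examples(self, x, want):
        assert count_zero_crossings(np.asarray(x, dtype=float)) == want

    @given(st.lists(st.sampled_from([-2.0, -1.0, 0.0, 1.0, 2.0]), min_size=2, max_size=30))
    def test_matches_naive_zero_skipping_scan(self, xs):
        x = np.asarray(xs)
        nz = [v for v in xs if v != 0]
        naive = sum(1 for a, b in zip(nz, nz[1:]) if (a > 0) != (b > 0))
        assert count_zero_crossings(x) == naive


class TestMedianAggregation:
    def test_aggregate_lies_within_per_window_range(self):
        # envelope computed independently by slicing the bout-wide scaled
        # channels (derivatives are taken over the whole bout, as in the
        # pipeline) and applying plain numpy/scipy statistics per window
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        fs, T, k = 100.0, 1.0, 5
        n = int(k * T * fs)
        gyr = np.abs(rng.normal(80, 30, size=(n, 3)))
        acc = rng.normal(0, 0.2, size=(n, 3)) + [0, 1, 0]
        rec = ImuRecording("w", fs, gyr, acc)
        agg = extract_features(rec, T)

        gn = np.linalg.norm(gyr, axis=1)
        an = np.linalg.norm(acc, axis=1)
        channels = {
            "gyr_norm": gn * T,
            "acc_norm": an * T,
            "gyr_norm_deriv": np.gradient(gn, 1 / fs) * T,
            "acc_norm_deriv": np.gradient(an, 1 / fs) * T,
        }
        funcs = {
            "min": np.min,
            "max": np.max,
            "iqr": lambda x: np.subtract(*np.percentile(x, [75, 25])),
            "p10": lambda x: np.percentile(x, 10),
            "p90": lambda x: np.percentile(x, 90),
            "mean": np.mean,
            "median": np.median,
            "kurtosis": lambda x: sps.kurtosis(x, fisher=False, bias=True),
            "skewness": lambda x: sps.skew(x, bias=True),
            "std": lambda x: np.std(x, ddof=1),
            "mad": lambda x: np.mean(np.abs(x - x.mean())),
        }
        w = int(T * fs)
        for ch, sig in channels.items():
            for stat, fn in funcs.items():
                vals = [fn(sig[i * w:(i + 1) * w]) for i in range(k)]
                name = f"{ch}_{stat}"
                assert min(vals) - 1e-9 <= agg.values[name] <= max(vals) + 1e-9, name


class TestOrientationInvariance:
    def test_features_identical_under_rotation(self):
        bout = generate_bout(SimConfig(seed=9), 0, stride_time=1.1, n_cycles=6)
        rec = lowpass_filter(bout.recordings["shank_right"])
        base = extract_features(rec, 1.1).values
        rng = np.random.default_rng(5)
        for _ in range(5):
            rot = extract_features(rec.rotated(random_rotation(rng)), 1.1).values
            for name in FEATURE_NAMES:
                assert rot[name] == pytest.approx(base[name], rel=1e-9, abs=1e-9), name


class TestSpeedScaling:
    def test_scaling_shrinks_within_segment_spread_and_grows_separation(self):
        # the simulated analog of the boxplot argument for stride scaling:
        # max|Gyr| of the same segment across speeds varies less after
        # scaling, while foot and thigh move further apart
        cfg = SimConfig(seed=21, orientation_randomization=False,
                        gyr_noise_sd=0.0, acc_noise_sd=0.0, cycle_variability_sd=0.0)
        strides = np.linspace(0.6, 2.2, 7)
        raw = {"foot": [], "thigh": []}
        scaled = {"foot": [], "thigh": []}
        for T in strides:
            bout = generate_bout(cfg, 0, stride_time=float(T), n_cycles=4)
            for seg in raw:
                m = bout.recordings[f"{seg}_right"].gyr_norm().max()
                raw[seg].append(m)
                scaled[seg].append(m * T)
        for seg in raw:
            spread_raw = np.subtract(*np.percentile(raw[seg], [75, 25]))
            spread_scaled = np.subtract(*np.percentile(scaled[seg], [75, 25]))
            assert spread_scaled < spread_raw
        gap_raw = min(raw["foot"]) - max(raw["thigh"])
        gap_scaled = min(scaled["foot"]) - max(scaled["thigh"])
        assert gap_scaled > gap_raw


class TestZScore:
    def _vectors(self, rows):
        return [
            FeatureVector(values=dict(zip(("a", "b"), row)), window_count=1, stride_time=1.0)
            for row in rows
        ]

    def test_training_set_standardizes_to_zero_one(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 10.0, 30.0, 50.0]})
        params = fit_zscore(df)
        z = np.array([
            [apply_zscore({"a": a, "b": b}, params).values[k] for k in ("a", "b")]
            for a, b in zip(df["a"], df["b"])
        ])
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_training_mean_maps_to_zero_and_arithmetic(self):
        params = ZScoreParams(mean={"a": 2.0}, std={"a": 2.0})
        assert apply_zscore({"a": 2.0}, params).values["a"] == 0.0
        assert apply_zscore({"a": 6.0}, params).values["a"] == 2.0

    def test_zero_variance_feature_dropped_with_warning(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="flat"):
            params = fit_zscore(df)
        assert "flat" not in params.feature_names

    def test_missing_feature_at_apply_time_rejected(self):
        params = ZScoreParams(mean={"a": 0.0, "b": 0.0}, std={"a": 1.0, "b": 1.0})
        with pytest.raises(FeatureError, match="'b' missing"):
            apply_zscore({"a": 1.0}, params)
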