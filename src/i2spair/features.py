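"""Stride-scaled, orientation-invariant features of one sensor x one bout.

All statistics are computed on the norms |Gyr|, |Acc| and their time
derivatives |Gyr|', |Acc|' after multiplying each by the bout's mean stride
time.  Scaling removes most of the gait-speed dependence of signal
amplitude (a fast walker produces large amplitudes over a short stride and
vice versa), so the same thresholds learned by the classifier hold across
speeds.  The bout is cut into non-overlapping windows of one stride time
anchored at sample 0; each feature is computed per window and aggregated
across windows by the median, which discards outliers from gait initiation
and termination.

Catalog (51 features):

* 11 distribution statistics (min, max, iqr, p10, p90, mean, median,
  kurtosis, skewness, std, mad) x 4 scaled channels = 44;
* ``motionless_pct``: fraction of samples with unscaled |Gyr| < 10 deg/s and
  unscaled |Acc| < 1.3 g (physical thresholds, hence on unscaled signals);
* peak and valley counts of scaled |Gyr| and |Acc| (4);
* zero-crossing counts of |Gyr|' and |Acc|' (2).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .imu_signals import DerivedChannels, ImuRecording, derive_channels

STAT_NAMES = (
    "min", "max", "iqr", "p10", "p90", "mean",
    "median", "kurtosis", "skewness", "std", "mad",
)
CHANNEL_KEYS = ("gyr_norm", "acc_norm", "gyr_norm_deriv", "acc_norm_deriv")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{stat}" for ch in CHANNEL_KEYS for stat in STAT_NAMES
) + (
    "motionless_pct",
    "gyr_norm_n_peaks",
    "gyr_norm_n_valleys",
    "acc_norm_n_peaks",
    "acc_norm_n_valleys",
    "gyr_norm_deriv_n_zero_crossings",
    "acc_norm_deriv_n_zero_crossings",
)

#: the seven features of the default shipped segment model
DEFAULT_SEGMENT_FEATURES = (
    "gyr_norm_iqr",
    "acc_norm_deriv_kurtosis",
    "gyr_norm_deriv_n_zero_crossings",
    "acc_norm_min",
    "gyr_norm_min",
    "gyr_norm_deriv_skewness",
    "gyr_norm_deriv_mean",
)

GYR_MOTIONLESS_THRESHOLD = 10.0  # deg/s, on the unscaled gyroscope norm
ACC_MOTIONLESS_THRESHOLD = 1.3  # g, on the unscaled accelerometer norm
PEAK_PROMINENCE_FRACTION = 0.05  # of the window's range


class FeatureError(ValueError):
    pass


@dataclasses.dataclass
class FeatureVector:
    """Named scalar features for one sensor x one walking bout."""

    values: dict[str, float]
    window_count: int
    stride_time: float


@dataclasses.dataclass
class ZScoreParams:
    """Per-feature mean/std estimated on a training set (ddof=1).

    Zero-variance features are dropped at fit time with a warning; they
    carry no information and would divide by zero.
    """

    mean: dict[str, float]
    std: dict[str, float]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.mean)


def scale_by_stride(channels: DerivedChannels, stride_time: float) -> DerivedChannels:
    """Multiply every statistics channel by the mean stride time."""
    if stride_time <= 0:
        raise FeatureError(f"stride time must be positive, got {stride_time}")
    return DerivedChannels(
        gyr_norm=channels.gyr_norm * stride_time,
        acc_norm=channels.acc_norm * stride_time,
        gyr_norm_deriv=channels.gyr_norm_deriv * stride_time,
        acc_norm_deriv=channels.acc_norm_deriv * stride_time,
    )


def _moment_stats(x: np.ndarray) -> dict[str, float]:
    m = float(x.mean())
    d = x - m
    m2 = float(np.mean(d * d))
    if m2 > 0.0:
        skew = float(np.mean(d**3)) / m2**1.5
        kurt = float(np.mean(d**4)) / m2**2  # non-excess: normal -> 3
    else:  # degenerate (constant) window
        skew, kurt = 0.0, 3.0
    p10, q25, p50, q75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    n = x.size
    std = float(np.sqrt(m2 * n / (n - 1))) if n > 1 else 0.0
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "iqr": float(q75 - q25),
        "p10": float(p10),
        "p90": float(p90),
        "mean": m,
        "median": float(p50),
        "kurtosis": kurt,
        "skewness": skew,
        "std": std,
        "mad": float(np.mean(np.abs(d))),
    }


def _count_peaks(x: np.ndarray) -> int:
    rng = float(x.max() - x.min())
    if rng <= 0:
        return 0
    peaks, _ = sps.find_peaks(x, prominence=PEAK_PROMINENCE_FRACTION * rng)
    return int(peaks.size)


def count_zero_crossings(x: np.ndarray) -> int:
    """Sign changes between consecutive samples; a zero sample joins the
    following sign (a run of zeros between opposite signs counts once)."""
    s = np.sign(x).astype(int)
    for i in range(s.size - 2, -1, -1):
        if s[i] == 0:
            s[i] = s[i + 1]
    return int(np.sum(s[1:] * s[:-1] < 0))


def extract_features(rec: ImuRecording, stride_time: float) -> FeatureVector:
    """Windowed feature extraction for one (filtered) recording.

    Raises
    ------
    FeatureError
        If the bout is shorter than one stride (no complete window).
    """
    if stride_time <= 0:
        raise FeatureError(f"stride time must be positive, got {stride_time}")
    der = derive_channels(rec)
    w = int(round(stride_time * rec.fs))
    if w < 2 or rec.n_samples // w < 1:
        raise FeatureError(
            f"bout shorter than one stride ({rec.duration:.3f} s < {stride_time:.3f} s)"
        )
    n_win = rec.n_samples // w
    scaled = scale_by_stride(der, stride_time)
    per_window: list[dict[str, float]] = []
    for i in range(n_win):
        sl = slice(i * w, (i + 1) * w)
        feats: dict[str, float] = {}
        for key in CHANNEL_KEYS:
            stats = _moment_stats(getattr(scaled, key)[sl])
            for stat, value in stats.items():
                feats[f"{key}_{stat}"] = value
        motionless = (der.gyr_norm[sl] < GYR_MOTIONLESS_THRESHOLD) & (
            der.acc_norm[sl] < ACC_MOTIONLESS_THRESHOLD
        )
        feats["motionless_pct"] = float(np.mean(motionless))
        for key in ("gyr_norm", "acc_norm"):
            xw = getattr(scaled, key)[sl]
            feats[f"{key}_n_peaks"] = float(_count_peaks(xw))
            feats[f"{key}_n_valleys"] = float(_count_peaks(-xw))
        for key in ("gyr_norm_deriv", "acc_norm_deriv"):
            feats[f"{key}_n_zero_crossings"] = float(
                count_zero_crossings(getattr(scaled, key)[sl])
            )
        per_window.append(feats)
    values = {
        name: float(np.median([fw[name] for fw in per_window])) for name in FEATURE_NAMES
    }
    return FeatureVector(values=values, window_count=n_win, stride_time=stride_time)


def features_to_frame(
    vectors: Sequence[FeatureVector],
    labels: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame (plus optional label columns)."""
    df = pd.DataFrame([fv.values for fv in vectors], columns=list(FEATURE_NAMES))
    if labels:
        for name, col in labels.items():
            df[name] = list(col)
    return df


def fit_zscore(train: Sequence[FeatureVector] | pd.DataFrame) -> ZScoreParams:
    if isinstance(train, pd.DataFrame):
        df = train
    else:
        if len(train) < 2:
            raise FeatureError("z-score fitting needs at least 2 training vectors")
        df = features_to_frame(train)
    if df.shape[0] < 2:
        raise FeatureError("z-score fitting needs at least 2 training vectors")
    mean = df.mean(axis=0)
    std = df.std(axis=0, ddof=1)
    kept = std > 0
    dropped = [str(c) for c in df.columns[~kept]]
    if dropped:
        warnings.warn(
            f"dropping zero-variance features: {', '.join(dropped)}", stacklevel=2
        )
    return ZScoreParams(
        mean={str(c): float(mean[c]) for c in df.columns[kept]},
        std={str(c): float(std[c]) for c in df.columns[kept]},
    )


def apply_zscore(fv: FeatureVector | Mapping[str, float], params: ZScoreParams) -> FeatureVector:
    """Standardize a vector with *training* parameters (never re-fit)."""
    values = fv.values if isinstance(fv, FeatureVector) else dict(fv)
    out: dict[str, float] = {}
    for name in params.feature_names:
        if name not in values:
            raise FeatureError(f"feature {name!r} missing from vector at apply time")
        out[name] = (values[name] - params.mean[name]) / params.std[name]
    if isinstance(fv, FeatureVector):
        return FeatureVector(values=out, window_count=fv.window_count, stride_time=fv.stride_time)
    return FeatureVector(values=out, window_count=1, stride_time=float("nan"))
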