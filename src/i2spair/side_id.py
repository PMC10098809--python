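"""Left/right identification of lower-limb sensors.

Foot side is found by functional calibration followed by a 3-feature tree.
Calibration aligns the arbitrarily mounted sensor frame with the anatomical
foot frame (Y up, X along walking direction, Z from left to right for both
feet) using the movement itself:

1. rotate so that the mean accelerometer vector during foot flat (gravity
   reaction, +1 g) points along +Y;
2. PCA on the swing-phase gyroscope gives the dominant rotation axis —
   plantar/dorsiflexion, i.e. the mediolateral Z axis;
3. rotate about Y to align that axis with Z;
4. fix the Z direction with the sign of the pitch angular velocity just
   after foot flat: the hindfoot leaves the ground first in essentially all
   gait patterns, a negative rotation about Z; if the calibrated signal
   shows a positive sign, rotate 180 degrees about Y.

In the calibrated frame, internal rotation (Gyr_y), eversion (Gyr_x) and
lateral acceleration (Acc_z) at the push-off peak have opposite signs on
the two feet; their per-cycle values at the first |Gyr| peak after each
foot flat, medianed over the bout, feed a small decision tree.

Shank/thigh side then needs only the labeled foot: during that foot's flat
period the contralateral leg is swinging, so of the two shank (or thigh)
sensors the one with the *smaller* mean |Gyr| during foot flat is on the
same side as the foot.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .imu_signals import ImuRecording
from .segment_model import DecisionTreeModel, train_tree

FOOT_FLAT_GYR_THRESHOLD = 5.0  # deg/s
FOOT_FLAT_MIN_FRACTION = 0.15  # of the stride time
#: first post-foot-flat |Gyr| peak must be this prominent (x bout max |Gyr|)
PEAK_PROMINENCE_FRACTION = 0.20
#: PCA eigenvalue gap below which no dominant sagittal axis exists
PCA_GAP_TOLERANCE = 0.01
#: relative difference below which the shank/thigh pair rule is ambiguous
SIDE_AMBIGUITY_TOLERANCE = 0.05

SIDE_FEATURE_NAMES = ("gyr_x_at_peak", "gyr_y_at_peak", "acc_z_at_peak")


class SideIdError(RuntimeError):
    """Raised when side identification cannot proceed on the given signals."""


@dataclasses.dataclass
class FootFlatIntervals:
    """Disjoint, sorted [start, end) sample intervals of foot flat."""

    intervals: list[tuple[int, int]]
    stride_time: float


@dataclasses.dataclass
class CalibrationRotation:
    """Orthonormal rotation mapping sensor frame -> anatomical foot frame."""

    rotation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise SideIdError("calibration rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise SideIdError("calibration rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise SideIdError("calibration rotation must be proper (det +1)")
        self.rotation = R


@dataclasses.dataclass
class SideFeatures:
    """Median over gait cycles of the three side-discriminant values."""

    gyr_x_at_peak: float
    gyr_y_at_peak: float
    acc_z_at_peak: float

    def as_dict(self) -> dict[str, float]:
        return {
            "gyr_x_at_peak": self.gyr_x_at_peak,
            "gyr_y_at_peak": self.gyr_y_at_peak,
            "acc_z_at_peak": self.acc_z_at_peak,
        }


def detect_foot_flat(
    rec: ImuRecording,
    stride_time: float,
    threshold: float = FOOT_FLAT_GYR_THRESHOLD,
    min_fraction: float = FOOT_FLAT_MIN_FRACTION,
) -> FootFlatIntervals:
    """Maximal runs with |Gyr| < ``threshold`` lasting >= 15% of the stride.

    The gyroscope norm is frame-invariant, so this works on calibrated and
    uncalibrated recordings alike.  Failure to find any interval usually
    means the sensor is not on a foot (or gait is highly abnormal).
    """
    if stride_time <= 0:
        raise SideIdError(f"stride time must be positive, got {stride_time}")
    below = rec.gyr_norm() < threshold
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    min_len = min_fraction * stride_time * rec.fs
    intervals = [
        (int(s), int(e)) for s, e in zip(starts, ends) if (e - s) >= min_len - 1e-9
    ]
    if not intervals:
        raise SideIdError(
            f"no foot flat found (|Gyr| < {threshold} deg/s for >= "
            f"{min_fraction:.0%} of the stride)"
        )
    return FootFlatIntervals(intervals=intervals, stride_time=float(stride_time))


def _flat_mask(rec: ImuRecording, flats: FootFlatIntervals) -> np.ndarray:
    mask = np.zeros(rec.n_samples, dtype=bool)
    for s, e in flats.intervals:
        mask[s:e] = True
    return mask


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-12:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * (K @ K)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / s**2)


def _rot_y(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])


def _post_flat_peaks(
    gyr_norm: np.ndarray, flats: FootFlatIntervals, fs: float
) -> list[int]:
    """First prominent |Gyr| peak after each foot-flat interval."""
    prominence = PEAK_PROMINENCE_FRACTION * float(gyr_norm.max())
    n = gyr_norm.shape[0]
    out = []
    for i, (_, end) in enumerate(flats.intervals):
        stop = flats.intervals[i + 1][0] if i + 1 < len(flats.intervals) else n
        if stop - end < 3:
            continue
        peaks, _ = sps.find_peaks(gyr_norm[end:stop], prominence=prominence)
        if peaks.size:
            out.append(int(end + peaks[0]))
    return out


def functional_calibration(
    rec: ImuRecording,
    flats: FootFlatIntervals,
    pca_gap_tol: float = PCA_GAP_TOLERANCE,
) -> CalibrationRotation:
    """Estimate the sensor-to-anatomical rotation of a foot sensor.

    Raises
    ------
    SideIdError
        If the swing-phase PCA has no dominant axis (first two eigenvalues
        within ``pca_gap_tol`` relative) or no post-foot-flat peak exists
        for the sign check.
    """
    mask = _flat_mask(rec, flats)
    g = rec.acc[mask].mean(axis=0)
    if np.linalg.norm(g) < 1e-9:
        raise SideIdError("zero mean acceleration during foot flat")
    R1 = _rotation_between(g, np.array([0.0, 1.0, 0.0]))

    swing = rec.gyr[~mask]
    if swing.shape[0] < 3:
        raise SideIdError("not enough swing-phase samples for PCA")
    X = swing - swing.mean(axis=0)
    evals, evecs = np.linalg.eigh((X.T @ X) / X.shape[0])
    lam1, lam2 = float(evals[2]), float(evals[1])
    if lam1 <= 0 or (lam1 - lam2) < pca_gap_tol * lam1:
        raise SideIdError("degenerate PCA: no dominant sagittal rotation axis")
    v = R1 @ evecs[:, 2]
    R = _rot_y(-np.arctan2(v[0], v[2])) @ R1

    gz = rec.gyr @ R.T[:, 2]
    peaks = _post_flat_peaks(rec.gyr_norm(), flats, rec.fs)
    if not peaks:
        raise SideIdError("no |Gyr| peak after foot flat for the sign check")
    if float(np.median(gz[peaks])) > 0:
        R = _rot_y(np.pi) @ R
    return CalibrationRotation(rotation=R)


def apply_calibration(rec: ImuRecording, cal: CalibrationRotation) -> ImuRecording:
    """Rotate a recording into the anatomical foot frame."""
    return rec.rotated(cal.rotation)


def foot_side_features(
    rec_calibrated: ImuRecording, flats: FootFlatIntervals
) -> SideFeatures:
    """Per-cycle Gyr_x, Gyr_y, Acc_z at the first post-foot-flat |Gyr| peak.

    Cycles with no prominent peak between consecutive flats are skipped;
    if every cycle is skipped a :class:`SideIdError` is raised.
    """
    peaks = _post_flat_peaks(rec_calibrated.gyr_norm(), flats, rec_calibrated.fs)
    if not peaks:
        raise SideIdError("no |Gyr| peak after any foot-flat interval")
    idx = np.asarray(peaks)
    return SideFeatures(
        gyr_x_at_peak=float(np.median(rec_calibrated.gyr[idx, 0])),
        gyr_y_at_peak=float(np.median(rec_calibrated.gyr[idx, 1])),
        acc_z_at_peak=float(np.median(rec_calibrated.acc[idx, 2])),
    )


def train_foot_side_model(
    features: Sequence[SideFeatures] | np.ndarray,
    sides: Sequence[str],
    random_state: int = 0,
) -> DecisionTreeModel:
    """Fit the 3-feature left/right tree on calibrated foot bouts."""
    import pandas as pd

    if len(features) != len(sides):
        raise SideIdError("features and sides must have equal lengths")
    if isinstance(features, np.ndarray):
        X = pd.DataFrame(features, columns=list(SIDE_FEATURE_NAMES))
    else:
        X = pd.DataFrame([sf.as_dict() for sf in features])
    return train_tree(
        X, list(sides), list(SIDE_FEATURE_NAMES), zscore=None,
        min_samples_leaf=1, random_state=random_state,
    )


def classify_foot_side(
    features: SideFeatures, model: Optional[DecisionTreeModel]
) -> str:
    if model is None:
        raise SideIdError("foot-side model is untrained")
    return model.predict(features.as_dict())


def assign_limb_side(
    pair: Mapping[str, ImuRecording],
    foot_rec: ImuRecording,
    foot_side: str,
    stride_time: float,
    ambiguity_tol: float = SIDE_AMBIGUITY_TOLERANCE,
) -> dict[str, str]:
    """Assign sides to a shank (or thigh) pair from one labeled foot.

    The pair member with the smaller mean |Gyr| during the foot's flat
    period shares the foot's side.  Means within ``ambiguity_tol`` relative
    of each other signal corrupted synchrony and raise an error.
    """
    if len(pair) != 2:
        raise SideIdError(f"exactly two pair members required, got {len(pair)}")
    if foot_side not in ("left", "right"):
        raise SideIdError(f"foot side must be 'left' or 'right', got {foot_side!r}")
    flats = detect_foot_flat(foot_rec, stride_time)
    mask = _flat_mask(foot_rec, flats)
    means: dict[str, float] = {}
    for sid, rec in pair.items():
        if rec.n_samples < mask.shape[0]:
            raise SideIdError(f"pair member {sid!r} does not cover the foot-flat samples")
        means[sid] = float(rec.gyr_norm()[: mask.shape[0]][mask].mean())
    (id_a, m_a), (id_b, m_b) = means.items()
    hi = max(m_a, m_b)
    if hi <= 0 or abs(m_a - m_b) <= ambiguity_tol * hi:
        raise SideIdError(
            f"ambiguous side: mean |Gyr| during foot flat {m_a:.2f} vs {m_b:.2f}"
        )
    other = "left" if foot_side == "right" else "right"
    if m_a < m_b:
        return {id_a: foot_side, id_b: other}
    return {id_b: foot_side, id_a: other}
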