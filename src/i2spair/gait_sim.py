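"""Synthetic 8-sensor walking bouts with known segment, side and stride time.

The generator emulates the *structural* properties of gait IMU signals that
the pairing pipeline exploits; it is not a forward-dynamics model:

* periodic, stride-locked waveforms built from smooth per-cycle bumps;
* amplitude ordering foot > shank > thigh > sacrum ~ trunk, with every
  amplitude proportional to 1/stride_time (faster gait, larger signals) so
  that unscaled features are genuinely speed-confounded;
* a foot-flat interval in which the foot barely moves (|Gyr| under a few
  deg/s), followed by a negative hindfoot-lift/push-off transient in Gyr_z;
* anatomical sign conventions at push-off: positive Gyr_y (internal
  rotation), Gyr_x (eversion) and Acc_z (lateral acceleration) for the
  right foot, mirrored on the left; plantar flexion negative in Gyr_z on
  both sides;
* left-side signals are the sagittal mirror of the right shifted by half a
  stride; pelvis (sacrum) and trunk move predominantly at the *step*
  frequency (2 per stride), which reproduces the halved stride-time
  candidates the fusion step must reject;
* gravity (+1 g) on the anatomical Y axis of the accelerometer;
* each sensor is finally rotated by an independent uniform random rotation
  and gets white measurement noise;
* per-subject random amplitude/timing/foot-flat factors, so subject-wise
  train/dev splits are meaningful.

A pathology switch emulates deviated gait (shorter foot flat, asymmetric
amplitudes) for held-out "patient" cohorts.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .imu_signals import ImuRecording, save_recording

#: sensor roster of a full bout: (segment, side or None)
SENSOR_ROSTER: tuple[tuple[str, Optional[str]], ...] = (
    ("foot", "right"), ("foot", "left"),
    ("shank", "right"), ("shank", "left"),
    ("thigh", "right"), ("thigh", "left"),
    ("sacrum", None), ("trunk", None),
)


def sensor_name(segment: str, side: Optional[str]) -> str:
    return f"{segment}_{side}" if side else segment


@dataclasses.dataclass
class SimConfig:
    """Study conditions of a simulated cohort.

    Defaults follow the conditions of the walking protocol the pipeline is
    built for: 200 Hz sampling, bouts of 2-10 gait cycles, stride times
    uniform on 0.45-2.4 s (covering ~0.5-2.2 m/s walking), arbitrary sensor
    orientation, and modest sensor noise (1 deg/s gyro, 0.02 g acc).
    """

    n_subjects: int = 10
    bouts_per_subject: int = 6
    stride_time_range: tuple[float, float] = (0.45, 2.4)
    cycles_range: tuple[int, int] = (2, 10)
    fs: float = 200.0
    gyr_noise_sd: float = 1.0  # deg/s
    acc_noise_sd: float = 0.02  # g
    #: stride-to-stride amplitude variability (SD of the per-cycle gain);
    #: real gait is never exactly periodic, and the time-domain stride
    #: estimator relies on that (perfectly periodic signals make half-stride
    #: windows cancel exactly under the median)
    cycle_variability_sd: float = 0.05
    orientation_randomization: bool = True
    pathology: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.bouts_per_subject < 1:
            raise ValueError("n_subjects and bouts_per_subject must be >= 1")
        lo, hi = self.stride_time_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid stride_time_range {self.stride_time_range}")
        clo, chi = self.cycles_range
        if clo < 2 or chi < clo:
            raise ValueError("cycles_range must satisfy 2 <= lo <= hi")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.gyr_noise_sd < 0 or self.acc_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")


@dataclasses.dataclass
class SyntheticBout:
    """One labeled walking bout: 8 sensor recordings plus ground truth."""

    subject_id: str
    bout_index: int
    recordings: dict[str, ImuRecording]
    truth: dict[str, tuple[str, Optional[str]]]
    true_stride_time: float
    n_cycles: int
    applied_rotations: dict[str, np.ndarray]
    #: clean anatomical-frame recordings (pre-rotation, pre-noise), kept for
    #: assertions on the constructed sign conventions
    anatomical: dict[str, ImuRecording]


@dataclasses.dataclass
class _SubjectParams:
    amp: float  # global amplitude factor
    seg_amp: dict[str, float]  # per-segment factor
    jitter: float  # bump-center timing offset (cycle fraction)
    flat_fraction: float  # foot-flat duration as cycle fraction
    left_amp: float  # left-side amplitude asymmetry (pathology < 1)


def _subject_params(config: SimConfig, subject_index: int) -> _SubjectParams:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11, subject_index]))
    amp = float(np.exp(rng.normal(0.0, 0.08)))
    # pelvis/trunk amplitudes vary more between people than limb amplitudes
    # (posture, soft-tissue attachment), which is where real segment
    # confusion happens
    seg_amp = {
        seg: float(np.exp(rng.normal(0.0, 0.08 if seg in ("sacrum", "trunk") else 0.05)))
        for seg in ("foot", "shank", "thigh", "sacrum", "trunk")
    }
    jitter = float(rng.normal(0.0, 0.008))
    if config.pathology:
        flat_fraction = float(rng.uniform(0.17, 0.23))
        left_amp = float(rng.uniform(0.85, 0.95))
    else:
        flat_fraction = float(rng.uniform(0.22, 0.32))
        left_amp = 1.0
    return _SubjectParams(
        amp=amp, seg_amp=seg_amp, jitter=jitter,
        flat_fraction=flat_fraction, left_amp=left_amp,
    )


def _bump(u: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit cycle."""
    d = (u - center + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / width) ** 2)


def _plateau(u: np.ndarray, a: float, b: float, tau: float = 0.008) -> np.ndarray:
    """Smooth indicator of u in [a, b] (periodic via +-1 images)."""
    out = np.zeros_like(u)
    for k in (-1.0, 0.0, 1.0):
        uk = u + k
        out += 1.0 / (1.0 + np.exp(-(uk - a) / tau)) / (1.0 + np.exp(-(b - uk) / tau))
    return np.clip(out, 0.0, 1.0)


# anatomical-frame right-side waveform builders -----------------------------
#
# u is the cycle phase in [0, 1); foot flat occupies [FLAT_START,
# FLAT_START + flat_fraction].  Amplitudes are deg/s (gyro) and g (acc) at a
# reference stride of 1 s and scale with 1/stride_time.

FLAT_START = 0.05

#: dense reference grid over one exact cycle, used to balance each gyro
#: axis to zero net rotation per *period* (a bout's partial boundary tail
#: must not leak into the correction)
_U_REF = np.arange(2000) / 2000.0


def _foot_right(u, amp, aamp, ff, jit, ws):
    # ws >= 1 widens the sharp transient bumps (push-off, landing) at fast
    # strides: transient durations do not shrink proportionally with the
    # cycle, while swing-phase rotations do and keep their cycle fraction
    n_bout = u.shape[0]
    u = np.concatenate([u, _U_REF])
    fs0, fe = FLAT_START, FLAT_START + ff
    # sharp stance envelope: ff is the *detectable* flat fraction, so the
    # transition edges must not eat into the below-threshold run
    env = 1.0 - _plateau(u, fs0 - 0.01, fe + 0.01, tau=0.003)
    c_p = fe + 0.07 + jit  # push-off (hindfoot lift)
    c_s = fe + 0.30 + jit  # mid-swing
    c_t = 0.015  # terminal-swing landing transient
    gz = amp * (-1.25 * _bump(u, c_p, 0.035 * ws) + 1.0 * _bump(u, c_s, 0.08)
                - 0.55 * _bump(u, c_t, 0.03 * ws))
    gy = 0.42 * amp * (_bump(u, c_p, 0.04 * ws) - 0.25 * _bump(u, c_s, 0.09))
    gx = 0.33 * amp * (_bump(u, c_p, 0.045 * ws) - 0.2 * _bump(u, c_s + 0.05, 0.09))
    ax = aamp * (0.9 * _bump(u, c_p, 0.05 * ws) - 0.5 * _bump(u, c_s, 0.09)
                 + 0.6 * _bump(u, c_t, 0.035 * ws))
    ay = aamp * (1.1 * _bump(u, c_p, 0.045 * ws) + 0.5 * _bump(u, c_t, 0.03 * ws)
                 - 0.3 * _bump(u, c_s, 0.10))
    az = aamp * (0.9 * _bump(u, c_p, 0.05 * ws) + 0.25 * _bump(u, c_s + 0.03, 0.10))
    gyr = np.column_stack([gx, gy, gz]) * env[:, None]
    # the sensor orientation is periodic over a gait cycle, so each gyro
    # axis must integrate to ~zero per cycle; remove the net rotation by an
    # env-shaped correction (template means, so the foot-flat interval and
    # the bout's partial tail stay untouched)
    ref_gyr, ref_env = gyr[n_bout:], env[n_bout:]
    correction = ref_gyr.mean(axis=0) / ref_env.mean()
    gyr = gyr[:n_bout] - correction * env[:n_bout, None]
    acc = np.column_stack([ax, ay, az]) * env[:, None]
    acc = acc[:n_bout]
    acc[:, 1] += 1.0  # gravity on anatomical Y
    return gyr, acc


def _shank_right(u, amp, aamp, ff, jit, ws):
    n_bout = u.shape[0]
    u = np.concatenate([u, _U_REF])
    # one dominant swing rotation and one stance reversal per stride; the
    # shank mainly feels its own once-per-stride events, so the stride
    # fundamental dominates every axis
    fe = FLAT_START + ff
    c_po = fe + 0.08 + jit
    c_sw = fe + 0.32 + jit
    gz = amp * (1.0 * _bump(u, c_sw, 0.12) - 0.45 * _bump(u, c_po, 0.06 * ws)
                - 0.30 * _bump(u, 0.02, 0.06 * ws))
    # a small circular component keeps the shank rotating throughout stance
    # (|Gyr| never drops to zero on a walking shank)
    gx = 0.25 * amp * _bump(u, c_sw + 0.03, 0.14) + 0.08 * amp * np.cos(2 * np.pi * u)
    gy = 0.18 * amp * _bump(u, c_sw - 0.05, 0.14) + 0.08 * amp * np.sin(2 * np.pi * u)
    # sharp heel-strike impact: the shank is first in line above the foot,
    # so its acceleration carries a short high-jerk transient every stride
    ax = aamp * (0.9 * _bump(u, c_sw, 0.13) - 0.55 * _bump(u, 0.03, 0.04 * ws))
    ay = aamp * (0.8 * _bump(u, c_sw + 0.05, 0.14) + 0.55 * _bump(u, 0.03, 0.035 * ws))
    az = aamp * (0.6 * _bump(u, c_sw + 0.08, 0.15) + 0.2 * np.sin(2 * np.pi * u + 0.4))
    gyr = np.column_stack([gx, gy, gz])
    gyr = gyr[:n_bout] - gyr[n_bout:].mean(axis=0)  # zero net rotation per cycle
    acc = np.column_stack([ax, ay, az])
    acc = acc[:n_bout] - acc[n_bout:].mean(axis=0)
    acc[:, 1] += 1.0
    return gyr, acc


def _thigh_right(u, amp, aamp, ff, jit, ws):
    n_bout = u.shape[0]
    u = np.concatenate([u, _U_REF])
    fe = FLAT_START + ff
    c_sw = fe + 0.34 + jit
    # each rotation reverses within the same part of the cycle (flexion in
    # swing, extension back), so every axis is a balanced bump pair: the
    # cycle integral is ~zero by construction and the rectified norm shows
    # one dominant hump per stride (strong stride fundamental)
    gz = amp * (1.0 * _bump(u, c_sw - 0.08, 0.10) - 0.8 * _bump(u, c_sw + 0.10, 0.125)
                - 0.15 * _bump(u, 0.02, 0.07 * ws) + 0.15 * _bump(u, 0.12, 0.07 * ws))
    gx = (0.22 * amp * (_bump(u, c_sw - 0.04, 0.12) - _bump(u, c_sw + 0.14, 0.12))
          + 0.04 * amp * np.cos(2 * np.pi * u))
    gy = (0.16 * amp * (_bump(u, c_sw + 0.04, 0.12) - _bump(u, c_sw - 0.14, 0.12))
          + 0.04 * amp * np.sin(2 * np.pi * u))
    # the knee's soft tissue damps impact transients: thigh accelerations
    # are smooth compared to the shank's heel-strike spike
    ax = aamp * (0.8 * _bump(u, c_sw, 0.14) - 0.4 * _bump(u, 0.12, 0.12))
    ay = aamp * (0.7 * _bump(u, c_sw - 0.06, 0.15) + 0.3 * _bump(u, 0.04, 0.10))
    az = aamp * (0.5 * _bump(u, c_sw, 0.16) + 0.2 * np.sin(2 * np.pi * u + 1.3))
    gyr = np.column_stack([gx, gy, gz])
    gyr = gyr[:n_bout] - gyr[n_bout:].mean(axis=0)  # zero net rotation per cycle
    acc = np.column_stack([ax, ay, az])
    acc = acc[:n_bout] - acc[n_bout:].mean(axis=0)
    acc[:, 1] += 1.0
    return gyr, acc


def _pelvis_trunk(u, amp, aamp, phases, sharp):
    """Shared sacrum/trunk builder: step-frequency dominated oscillations.

    Tilt (Gyr_z) and the vertical/walking-direction accelerations move once
    per *step* (twice per stride) and carry the largest amplitudes, so the
    dominant spectral peak of most rotated channels sits at the step
    frequency — the halved-candidate failure mode.  Obliquity (Gyr_x),
    axial rotation (Gyr_y) and lateral sway (Acc_z) are stride-periodic,
    as in real pelvis/trunk kinematics, so some channels do expose the true
    stride frequency.
    """
    p = phases
    gx = amp * (0.55 * np.sin(2 * np.pi * u + p[0]) + 0.30 * np.sin(4 * np.pi * u + p[1]))
    gy = amp * (0.45 * np.sin(2 * np.pi * u + p[2]) + 0.25 * np.sin(4 * np.pi * u + p[3]))
    gz = amp * (1.0 * np.sin(4 * np.pi * u + p[4]) + 0.20 * np.sin(2 * np.pi * u + p[5]))
    ax = aamp * (0.6 * np.sin(4 * np.pi * u + p[6]) + 0.15 * np.sin(2 * np.pi * u + p[7]))
    ay = aamp * (1.0 * np.sin(4 * np.pi * u + p[8]) + sharp * np.sin(8 * np.pi * u + p[9]))
    az = aamp * (0.45 * np.sin(2 * np.pi * u + p[10]) + 0.20 * np.sin(4 * np.pi * u + p[11]))
    gyr = np.column_stack([gx, gy, gz])
    acc = np.column_stack([ax, ay, az])
    acc[:, 1] += 1.0
    return gyr, acc


_SACRUM_PHASES = (0.3, 1.1, 2.0, 0.6, 1.5, 2.4, 0.9, 1.8, 0.1, 2.7, 1.2, 0.4)
_TRUNK_PHASES = (1.9, 0.2, 0.8, 2.2, 0.5, 1.4, 2.9, 0.7, 1.6, 2.1, 0.3, 2.6)

#: gyro amplitude (deg/s) and acc amplitude (g) at a 1 s stride
_SEGMENT_SCALE = {
    "foot": (380.0, 0.40),
    "shank": (200.0, 0.28),
    "thigh": (100.0, 0.18),
    "sacrum": (26.0, 0.22),
    "trunk": (16.0, 0.15),
}


def _mirror_arrays(gyr: np.ndarray, acc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return gyr * np.array([-1.0, -1.0, 1.0]), acc * np.array([1.0, 1.0, -1.0])


def _anatomical_waveform(
    segment: str, side: Optional[str], u: np.ndarray,
    stride_time: float, sp: _SubjectParams,
) -> tuple[np.ndarray, np.ndarray]:
    base_g, base_a = _SEGMENT_SCALE[segment]
    speed = 1.0 / stride_time
    amp = base_g * speed * sp.amp * sp.seg_amp[segment]
    aamp = base_a * speed * sp.amp * sp.seg_amp[segment]
    if side == "left":
        amp *= sp.left_amp
        aamp *= sp.left_amp
        u = (u + 0.5) % 1.0
    ws = 1.0 / min(stride_time, 1.0)  # event-duration floor at fast strides
    if segment == "foot":
        gyr, acc = _foot_right(u, amp, aamp, sp.flat_fraction, sp.jitter, ws)
    elif segment == "shank":
        gyr, acc = _shank_right(u, amp, aamp, sp.flat_fraction, sp.jitter, ws)
    elif segment == "thigh":
        gyr, acc = _thigh_right(u, amp, aamp, sp.flat_fraction, sp.jitter, ws)
    elif segment == "sacrum":
        gyr, acc = _pelvis_trunk(u, amp, aamp, _SACRUM_PHASES, 0.35)
    elif segment == "trunk":
        gyr, acc = _pelvis_trunk(u, amp, aamp, _TRUNK_PHASES, 0.10)
    else:
        raise ValueError(f"unknown segment {segment!r}")
    if side == "left":
        gyr, acc = _mirror_arrays(gyr, acc)
    return gyr, acc


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_bout(
    config: SimConfig,
    subject_id: Union[str, int],
    stride_time: Optional[float] = None,
    n_cycles: Optional[int] = None,
    bout_index: int = 0,
) -> SyntheticBout:
    """Generate one labeled 8-sensor bout.

    Everything random is keyed on ``(config.seed, subject, bout_index)``, so
    the same arguments always reproduce the same bout.
    """
    if isinstance(subject_id, str):
        sindex = int("".join(ch for ch in subject_id if ch.isdigit()) or 0)
        sid = subject_id
    else:
        sindex = int(subject_id)
        sid = f"S{sindex:03d}"
    sp = _subject_params(config, sindex)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23, sindex, bout_index]))
    if stride_time is None:
        stride_time = float(rng.uniform(*config.stride_time_range))
    if n_cycles is None:
        n_cycles = int(rng.integers(config.cycles_range[0], config.cycles_range[1] + 1))
    if n_cycles < 2:
        raise ValueError("a bout must contain at least two gait cycles")

    # real bout boundaries are arbitrary relative to the gait cycle: a
    # partial extra cycle keeps window counts from aligning exactly with
    # the period (downstream feature windows discard the incomplete tail)
    extra = float(rng.uniform(0.1, 0.9))
    n = int(round((n_cycles + extra) * stride_time * config.fs))
    t = np.arange(n) / config.fs
    phase0 = float(rng.uniform(0.0, 1.0))
    u = (t / stride_time + phase0) % 1.0

    # shared stride-to-stride amplitude modulation: one gain per cycle,
    # constant within the cycle (so each cycle's gyro integral stays zero —
    # the sensor attitude is periodic no matter how strong the stride was),
    # common to all sensors of the bout (synchrony)
    phase_abs = t / stride_time + phase0
    if config.cycle_variability_sd > 0:
        gains = 1.0 + rng.normal(0.0, config.cycle_variability_sd, n_cycles + 2)
        modulation = gains[np.floor(phase_abs).astype(int)]
    else:
        modulation = np.ones(n)

    recordings: dict[str, ImuRecording] = {}
    anatomical: dict[str, ImuRecording] = {}
    truth: dict[str, tuple[str, Optional[str]]] = {}
    rotations: dict[str, np.ndarray] = {}
    for segment, side in SENSOR_ROSTER:
        name = sensor_name(segment, side)
        gyr, acc = _anatomical_waveform(segment, side, u, stride_time, sp)
        gyr = gyr * modulation[:, None]
        acc = (acc - [0.0, 1.0, 0.0]) * modulation[:, None] + [0.0, 1.0, 0.0]
        anatomical[name] = ImuRecording(sensor_id=name, fs=config.fs, gyr=gyr, acc=acc)
        R = _random_rotation(rng) if config.orientation_randomization else np.eye(3)
        g_obs = gyr @ R.T + rng.normal(0.0, config.gyr_noise_sd, size=gyr.shape)
        a_obs = acc @ R.T + rng.normal(0.0, config.acc_noise_sd, size=acc.shape)
        recordings[name] = ImuRecording(sensor_id=name, fs=config.fs, gyr=g_obs, acc=a_obs)
        truth[name] = (segment, side)
        rotations[name] = R
    return SyntheticBout(
        subject_id=sid,
        bout_index=bout_index,
        recordings=recordings,
        truth=truth,
        true_stride_time=float(stride_time),
        n_cycles=int(n_cycles),
        applied_rotations=rotations,
        anatomical=anatomical,
    )


def generate_dataset(config: SimConfig) -> tuple[list[SyntheticBout], pd.DataFrame]:
    """All bouts of a cohort plus a manifest table.

    The manifest has one row per sensor recording with subject, bout, sensor,
    segment, side and the true stride time.
    """
    bouts: list[SyntheticBout] = []
    rows = []
    for s in range(config.n_subjects):
        for b in range(config.bouts_per_subject):
            bout = generate_bout(config, s, bout_index=b)
            bouts.append(bout)
            for name, (segment, side) in bout.truth.items():
                rows.append(
                    {
                        "subject": bout.subject_id,
                        "bout": b,
                        "sensor": name,
                        "segment": segment,
                        "side": side if side else "",
                        "stride_time": bout.true_stride_time,
                        "n_cycles": bout.n_cycles,
                        "file": f"{bout.subject_id}_b{b:02d}_{name}.csv",
                    }
                )
    return bouts, pd.DataFrame(rows)


def write_dataset(
    bouts: Sequence[SyntheticBout], manifest: pd.DataFrame, outdir: Union[str, os.PathLike]
) -> None:
    """Write per-sensor CSV files (the imu_signals dialect) and manifest.csv."""
    os.makedirs(outdir, exist_ok=True)
    for bout in bouts:
        for name, rec in bout.recordings.items():
            fname = f"{bout.subject_id}_b{bout.bout_index:02d}_{name}.csv"
            save_recording(rec, os.path.join(outdir, fname))
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
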