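"""Core IMU signal model: recordings, filtering, norms/derivatives and file I/O.

An :class:`ImuRecording` holds one sensor's synchronous tri-axial angular
velocity (deg/s) and acceleration (g, gravity included) sampled at a known
rate.  Everything downstream (stride-time estimation, feature extraction,
side identification) consumes this container, so the unit conventions are
fixed here: angular velocity in deg/s, acceleration in g.  Files recorded in
m/s^2 can be converted on load (``acc_units="ms2"``).

The orientation-invariance backbone of the whole pipeline lives in
:func:`derive_channels`: the Euclidean norms of the gyroscope and
accelerometer are invariant under any rigid rotation of the sensor, so
features built from them do not depend on how the sensor was strapped on.
"""

from __future__ import annotations

import dataclasses
import io
import os
from typing import Union

import numpy as np
import pandas as pd
from scipy import signal as sps

GYR_COLS = ("Gyr_x", "Gyr_y", "Gyr_z")
ACC_COLS = ("Acc_x", "Acc_y", "Acc_z")
#: standard gravity, used to convert m/s^2 accelerations to g on load
G_MS2 = 9.80665


class SignalError(ValueError):
    """Raised for malformed input files or invalid signal operations."""


@dataclasses.dataclass
class ImuRecording:
    """One sensor's 6-channel time series.

    Parameters
    ----------
    sensor_id : str
        Free-form identifier (file stem, body location, ...).
    fs : float
        Sampling frequency in Hz.
    gyr : (N, 3) ndarray
        Angular velocity in deg/s, columns Gyr_x, Gyr_y, Gyr_z.
    acc : (N, 3) ndarray
        Acceleration in g (gravity included), columns Acc_x, Acc_y, Acc_z.
    """

    sensor_id: str
    fs: float
    gyr: np.ndarray
    acc: np.ndarray

    def __post_init__(self) -> None:
        self.gyr = np.asarray(self.gyr, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.fs <= 0:
            raise SignalError(f"sampling frequency must be positive, got {self.fs}")
        for name, arr in (("gyr", self.gyr), ("acc", self.acc)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise SignalError(f"{name} must be an (N, 3) array, got shape {arr.shape}")
        if self.gyr.shape[0] != self.acc.shape[0]:
            raise SignalError(
                f"gyr and acc sample counts differ: {self.gyr.shape[0]} vs {self.acc.shape[0]}"
            )
        if self.gyr.shape[0] < 2:
            raise SignalError("recording must contain at least 2 samples")
        for name, arr in (("gyr", self.gyr), ("acc", self.acc)):
            if not np.isfinite(arr).all():
                raise SignalError(f"non-finite samples in {name}")

    @property
    def n_samples(self) -> int:
        return self.gyr.shape[0]

    @property
    def duration(self) -> float:
        """Bout duration in seconds."""
        return self.n_samples / self.fs

    def gyr_norm(self) -> np.ndarray:
        return np.linalg.norm(self.gyr, axis=1)

    def acc_norm(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=1)

    def rotated(self, rotation: np.ndarray, sensor_id: str | None = None) -> "ImuRecording":
        """Apply a 3x3 rotation matrix to both vector channels (v -> R v)."""
        rotation = np.asarray(rotation, dtype=float)
        if rotation.shape != (3, 3):
            raise SignalError("rotation must be a 3x3 matrix")
        return ImuRecording(
            sensor_id=sensor_id if sensor_id is not None else self.sensor_id,
            fs=self.fs,
            gyr=self.gyr @ rotation.T,
            acc=self.acc @ rotation.T,
        )


def mirror_recording(rec: ImuRecording) -> ImuRecording:
    """Reflect a recording through the sagittal (x-y) plane, z -> -z.

    Acceleration is a true vector, so Acc_z changes sign; angular velocity is
    a pseudovector, so Gyr_x and Gyr_y change sign while Gyr_z does not.
    Applying this to an arbitrarily oriented sensor yields the signal the
    mirror-image (contralateral) movement would have produced, so every side
    label must flip while segment labels (norm-based) are untouched.
    """
    gyr = rec.gyr * np.array([-1.0, -1.0, 1.0])
    acc = rec.acc * np.array([1.0, 1.0, -1.0])
    return ImuRecording(sensor_id=rec.sensor_id, fs=rec.fs, gyr=gyr, acc=acc)


@dataclasses.dataclass
class DerivedChannels:
    """Norms and norm derivatives of one recording.

    ``gyr_norm``/``acc_norm`` are per-sample Euclidean norms (deg/s, g);
    the derivatives use central differences in the interior and one-sided
    differences at the endpoints (units deg/s^2 and g/s).
    """

    gyr_norm: np.ndarray
    acc_norm: np.ndarray
    gyr_norm_deriv: np.ndarray
    acc_norm_deriv: np.ndarray


def derive_channels(rec: ImuRecording) -> DerivedChannels:
    gn = rec.gyr_norm()
    an = rec.acc_norm()
    dt = 1.0 / rec.fs
    return DerivedChannels(
        gyr_norm=gn,
        acc_norm=an,
        gyr_norm_deriv=np.gradient(gn, dt),
        acc_norm_deriv=np.gradient(an, dt),
    )


def lowpass_filter(rec: ImuRecording, cutoff: float = 4.0, order: int = 4) -> ImuRecording:
    """Zero-phase low-pass Butterworth filter applied to all 6 channels.

    The filter is applied forward-backward (``sosfiltfilt``) so gait events
    (foot-flat edges, push-off peaks) are not delayed; the effective
    amplitude response is the squared one-pass Butterworth magnitude.
    """
    if cutoff >= rec.fs / 2:
        raise SignalError(f"cutoff {cutoff} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    try:
        gyr = sps.sosfiltfilt(sos, rec.gyr, axis=0)
        acc = sps.sosfiltfilt(sos, rec.acc, axis=0)
    except ValueError as exc:  # signal shorter than the filtfilt padding
        raise SignalError(f"signal too short for filter warm-up: {exc}") from exc
    return ImuRecording(sensor_id=rec.sensor_id, fs=rec.fs, gyr=gyr, acc=acc)


def _looks_numeric(token: object) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def load_recording(
    path: Union[str, os.PathLike, io.IOBase],
    fs: float,
    acc_units: str = "g",
    sensor_id: str | None = None,
) -> ImuRecording:
    """Read a delimited text file into an :class:`ImuRecording`.

    The file must be comma- or tab-delimited with at least six numeric
    columns in the order Gyr_x, Gyr_y, Gyr_z, Acc_x, Acc_y, Acc_z.  An
    optional header row is detected; when its names contain the tokens
    gyr/acc and x/y/z (any case) they override the column order.  An
    optional leading time column (strictly increasing, ~1/fs spacing) is
    detected and dropped.

    Parameters
    ----------
    acc_units : {"g", "ms2"}
        Unit of the acceleration columns; "ms2" values are divided by
        9.80665 on load.
    """
    if acc_units not in ("g", "ms2"):
        raise SignalError(f"acc_units must be 'g' or 'ms2', got {acc_units!r}")
    if sensor_id is None:
        sensor_id = os.path.splitext(os.path.basename(str(path)))[0] if not isinstance(path, io.IOBase) else "<stream>"
    import csv

    try:
        raw = pd.read_csv(path, sep=None, engine="python", header=None, comment="#", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SignalError(f"{sensor_id}: empty file or undetectable delimiter") from exc
    if raw.shape[0] == 0:
        raise SignalError(f"{sensor_id}: empty file")

    header: list[str] | None = None
    if any(not _looks_numeric(v) for v in raw.iloc[0]):
        header = [str(v).strip() for v in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
        if raw.shape[0] == 0:
            raise SignalError(f"{sensor_id}: file contains a header but no data rows")

    data = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(data.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        offset = 2 if header is not None else 1
        raise SignalError(
            f"{sensor_id}: non-numeric or missing value at row {int(r) + offset}, column {int(c) + 1}"
        )
    values = data.to_numpy(dtype=float)

    col_order: list[int] | None = None
    if header is not None:
        matched: dict[str, int] = {}
        for idx, name in enumerate(header):
            low = name.lower()
            for prefix, cols in (("gyr", GYR_COLS), ("acc", ACC_COLS)):
                if prefix in low:
                    for axis_i, axis in enumerate("xyz"):
                        if axis in low.replace(prefix, ""):
                            matched[cols[axis_i]] = idx
        wanted = list(GYR_COLS) + list(ACC_COLS)
        if all(w in matched for w in wanted):
            col_order = [matched[w] for w in wanted]

    if col_order is None:
        ncol = values.shape[1]
        if ncol < 6:
            raise SignalError(f"{sensor_id}: expected at least 6 signal columns, found {ncol}")
        start = 0
        if ncol >= 7:
            t = values[:, 0]
            dt = np.diff(t)
            if t.shape[0] >= 2 and np.all(dt > 0) and abs(np.median(dt) - 1.0 / fs) < 0.2 / fs:
                start = 1
        if values.shape[1] - start < 6:
            raise SignalError(f"{sensor_id}: expected 6 signal columns after the time column")
        col_order = list(range(start, start + 6))

    sig = values[:, col_order]
    gyr = sig[:, :3]
    acc = sig[:, 3:6]
    if acc_units == "ms2":
        acc = acc / G_MS2
    return ImuRecording(sensor_id=sensor_id, fs=float(fs), gyr=gyr, acc=acc)


def save_recording(rec: ImuRecording, path: Union[str, os.PathLike], time_column: bool = True) -> None:
    """Write a recording in the dialect :func:`load_recording` reads."""
    cols: dict[str, np.ndarray] = {}
    if time_column:
        cols["time"] = np.arange(rec.n_samples) / rec.fs
    for i, name in enumerate(GYR_COLS):
        cols[name] = rec.gyr[:, i]
    for i, name in enumerate(ACC_COLS):
        cols[name] = rec.acc[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
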