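"""Location-agnostic mean stride time of a walking bout.

Two independent estimators are combined.  In the frequency domain, the
amplitude spectrum of each of eight signals (three gyroscope axes, three
accelerometer axes and the two norms) yields a candidate stride time: the
inverse of the first spectral peak, scanning from low to high frequency,
whose in-band normalized amplitude reaches 0.5.  In the time domain, the
orientation of a sensor is (nearly) the same at the start and end of a gait
cycle, so the integral of each angular-velocity component over one cycle is
close to zero: sweeping a window size WS from 0.3 s upward in 1/fs steps,
the residual

    Res(WS) = sqrt(med_x^2 + med_y^2 + med_z^2)

(with med_* the median over non-overlapping windows of the per-window
integral of that gyro axis) is minimized at window sizes equal to the stride
time.  The fused estimate is the FFT candidate closest to the residual
minimizer — the residual curve has 1/fs resolution but can lock onto
multiples of the period, while FFT candidates are precise but can sit at the
step frequency (half a stride) on trunk/sacrum-like signals; each estimator
vetoes the other's characteristic failure.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import integrate as spi
from scipy import signal as sps

from .imu_signals import ImuRecording

#: fixed channel order; also the tie-break order for fusion
CHANNEL_ORDER = ("Gyr_x", "Gyr_y", "Gyr_z", "|Gyr|", "Acc_x", "Acc_y", "Acc_z", "|Acc|")

#: admissible stride-frequency band (Hz): covers 0.5-2.2 m/s walking while
#: excluding DC leakage
FREQ_BAND = (0.3, 3.5)
#: minimum normalized spectral amplitude for a qualifying peak
PEAK_THRESHOLD = 0.5
#: initial window size of the residual sweep (s); strides are always longer
WS_START = 0.3
#: upper window size of the residual sweep (s), also capped at duration/2
WS_MAX = 3.0


class StrideTimeError(ValueError):
    """Raised when a bout is too short for stride-time estimation."""


@dataclasses.dataclass
class FftCandidates:
    """Per-channel stride-time candidates (s); channels with no qualifying
    spectral peak are absent."""

    per_channel: dict[str, float]


@dataclasses.dataclass
class ResidualCurve:
    """Residual of the gyroscope-integral analysis versus window size."""

    window_sizes: np.ndarray  # s, spaced exactly 1/fs
    residuals: np.ndarray  # deg, >= 0
    chosen_index: int
    estimate: float  # s, == window_sizes[chosen_index]


@dataclasses.dataclass
class StrideTimeEstimate:
    fft: FftCandidates
    residual: ResidualCurve
    mean_stride_time: float
    chosen_channel: Optional[str]


def _channel_signals(rec: ImuRecording) -> dict[str, np.ndarray]:
    out = {name: rec.gyr[:, i] for i, name in enumerate(CHANNEL_ORDER[:3])}
    out["|Gyr|"] = rec.gyr_norm()
    for i, name in enumerate(CHANNEL_ORDER[4:7]):
        out[name] = rec.acc[:, i]
    out["|Acc|"] = rec.acc_norm()
    return out


def fft_candidates(
    rec: ImuRecording,
    band: tuple[float, float] = FREQ_BAND,
    threshold: float = PEAK_THRESHOLD,
) -> FftCandidates:
    """First qualifying spectral peak of each of the 8 channels.

    Each channel is mean-removed (the accelerometer carries a gravity DC
    component that would otherwise dominate), zero-padded for a fine
    frequency grid, and its amplitude spectrum normalized to a maximum of 1
    inside the admissible band.  Scanning from low to high frequency, the
    first strict local maximum with normalized amplitude >= ``threshold``
    defines the candidate stride time 1/f.
    """
    n = rec.n_samples
    # zero-pad for ~0.01 Hz bin spacing so candidates are not grid-limited
    nfft = 1 << int(np.ceil(np.log2(max(n, rec.fs / 0.01))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    f_band = freqs[in_band]
    out: dict[str, float] = {}
    for name, x in _channel_signals(rec).items():
        x = x - x.mean()
        # a channel carrying no signal (numerically constant) has nothing
        # to normalize; 1e-6 deg/s / g is far below any real sensor noise
        if np.sqrt(np.mean(x * x)) < 1e-6:
            continue
        amp = np.abs(np.fft.rfft(x, n=nfft))[in_band]
        m = amp.max()
        if m <= 0:
            continue
        amp = amp / m
        peaks, _ = sps.find_peaks(amp)
        qualifying = peaks[amp[peaks] >= threshold]
        if qualifying.size:
            out[name] = 1.0 / f_band[qualifying[0]]
    return FftCandidates(per_channel=out)


def residual_estimate(
    rec: ImuRecording,
    ws_start: float = WS_START,
    ws_max: float = WS_MAX,
) -> ResidualCurve:
    """Gyroscope-integral residual sweep over window sizes.

    For every window size WS on the 1/fs grid starting at ``ws_start``, the
    bout is tiled with non-overlapping windows [i*WS, (i+1)*WS]; the
    trapezoidal integral of each gyro axis over each window is reduced to a
    per-axis median, and the three medians combined as a Euclidean norm.
    The estimate is the smallest window size attaining the global minimum
    (within 1e-9 relative), which rejects the multiples of the period that
    are equally good minimizers.
    """
    fs = rec.fs
    n = rec.n_samples
    w0 = int(round(ws_start * fs))
    if w0 < 2:
        raise StrideTimeError("window grid degenerate: fs too low for ws_start")
    if n < 2 * w0:
        raise StrideTimeError(
            f"bout too short: {n / fs:.3f} s < {2 * ws_start:.3f} s (two minimal windows)"
        )
    wmax = int(round(min(ws_max, n / fs / 2.0) * fs))
    wmax = max(wmax, w0)
    cum = spi.cumulative_trapezoid(rec.gyr, dx=1.0 / fs, axis=0, initial=0.0)
    widths = np.arange(w0, wmax + 1)
    residuals = np.empty(widths.shape[0])
    for k, w in enumerate(widths):
        starts = np.arange(0, n - w, w)
        ints = np.sort(cum[starts + w] - cum[starts], axis=0)
        m = ints.shape[0]
        if m % 2:
            med = ints[m // 2]
        else:
            med = 0.5 * (ints[m // 2 - 1] + ints[m // 2])
        residuals[k] = float(np.sqrt(np.sum(med * med)))
    rmin = residuals.min()
    chosen = int(np.argmax(residuals <= rmin * (1.0 + 1e-9)))
    window_sizes = widths / fs
    return ResidualCurve(
        window_sizes=window_sizes,
        residuals=residuals,
        chosen_index=chosen,
        estimate=float(window_sizes[chosen]),
    )


def fuse(fft: FftCandidates, residual: ResidualCurve) -> StrideTimeEstimate:
    """Select the FFT candidate closest to the residual-analysis estimate.

    Ties are broken by the fixed channel order.  With no candidate at all
    (all spectra below threshold) the residual estimate is used directly,
    with a warning — this is a degraded, non-periodic-signal outcome.
    """
    best: Optional[str] = None
    best_err = np.inf
    for name in CHANNEL_ORDER:
        if name not in fft.per_channel:
            continue
        err = abs(fft.per_channel[name] - residual.estimate)
        if err < best_err:
            best, best_err = name, err
    if best is None:
        warnings.warn(
            "no qualifying FFT peak in any channel; falling back to the residual estimate",
            stacklevel=2,
        )
        return StrideTimeEstimate(
            fft=fft, residual=residual, mean_stride_time=residual.estimate, chosen_channel=None
        )
    return StrideTimeEstimate(
        fft=fft,
        residual=residual,
        mean_stride_time=float(fft.per_channel[best]),
        chosen_channel=best,
    )


def estimate_stride_time(rec: ImuRecording) -> StrideTimeEstimate:
    """Full single-sensor estimate: FFT candidates + residual sweep + fusion."""
    return fuse(fft_candidates(rec), residual_estimate(rec))


def fft_only_estimate(
    rec: ImuRecording, band: tuple[float, float] = FREQ_BAND
) -> Optional[float]:
    """Stride time from the dominant spectral frequencies alone.

    Per channel, the in-band frequency of maximum amplitude is inverted and
    the median over channels is returned — what the frequency analysis
    yields with no time-domain residual to arbitrate between the stride
    frequency and its harmonics.  Used for the comparison analysis showing
    why fusion is needed.
    """
    n = rec.n_samples
    nfft = 1 << int(np.ceil(np.log2(max(n, rec.fs / 0.01))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    f_band = freqs[in_band]
    cands = []
    for x in _channel_signals(rec).values():
        amp = np.abs(np.fft.rfft(x - x.mean(), n=nfft))[in_band]
        if amp.max() > 0:
            cands.append(1.0 / f_band[int(np.argmax(amp))])
    if not cands:
        return None
    return float(np.median(cands))


def bout_stride_time(recs: Sequence[ImuRecording] | Iterable[ImuRecording]) -> float:
    """Median of the fused per-sensor estimates of one walking bout.

    The median makes the bout value robust to the occasional sensor whose
    spectrum is dominated by the step frequency (sacrum/trunk), which yields
    a halved candidate.
    """
    recs = list(recs)
    if not recs:
        raise StrideTimeError("no recordings given")
    return float(np.median([estimate_stride_time(r).mean_stride_time for r in recs]))
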