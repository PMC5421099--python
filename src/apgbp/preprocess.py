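"""PPG signal conditioning: band-pass filtering, the acceleration
plethysmogram (APG, the second time-derivative of the PPG), beat
segmentation and pulse rate.

Conventions
-----------
Sample indices are 0-based; beats are half-open ``[onset, end)`` where
``end`` is the next beat's onset.  The APG keeps the length and sampling
rate of its source signal; samples inside the differentiator half-window
at either boundary are flagged invalid rather than extrapolated.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InputError, UndefinedPulseRateError

__all__ = [
    "PPGSignal",
    "APGSignal",
    "Beat",
    "bandpass",
    "second_derivative",
    "first_derivative",
    "segment_beats",
    "pulse_rate",
    "read_ppg_csv",
    "write_ppg_csv",
]


@dataclass
class PPGSignal:
    """Uniformly sampled photoplethysmogram.

    Parameters
    ----------
    samples : ndarray
        Signal amplitude in arbitrary units.
    fs : float
        Sampling rate in Hz (the wrist sensor samples at 100 Hz).
    t0 : optional
        Timestamp of the first sample; purely informational.
    """

    samples: np.ndarray
    fs: float
    t0: object = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InputError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise InputError("PPG samples must be one-dimensional")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class APGSignal:
    """Acceleration plethysmogram (second derivative of a PPG), a.u./s^2."""

    samples: np.ndarray
    fs: float
    edge: int = 0  # number of boundary samples per side that are invalid

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.samples.size, dtype=bool)
        if self.edge > 0:
            mask[: self.edge] = False
            mask[-self.edge :] = False
        return mask


@dataclass(frozen=True)
class Beat:
    """One segmented beat: half-open sample interval [onset, end)."""

    onset: int
    end: int
    fs: float

    @property
    def period(self) -> float:
        return (self.end - self.onset) / self.fs

    @property
    def onset_time(self) -> float:
        return self.onset / self.fs


def bandpass(ppg: PPGSignal, low: float = 0.3, high: float = 18.0) -> PPGSignal:
    """Zero-phase 4th-order Butterworth band-pass.

    The default band keeps the pulse fundamental and the harmonics that
    carry the APG's systolic curvature while rejecting baseline drift.
    DC is removed entirely (the output has ~zero mean).
    """
    if not 0 < low < high:
        raise InputError(f"need 0 < low < high, got ({low}, {high})")
    if high >= ppg.fs / 2:
        raise InputError(f"high cutoff {high} Hz is outside Nyquist ({ppg.fs / 2} Hz)")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=ppg.fs, output="sos")
    out = sps.sosfiltfilt(sos, ppg.samples)
    return PPGSignal(out, ppg.fs, ppg.t0)


def _savgol(x: np.ndarray, fs: float, deriv: int, window: int, polyorder: int) -> np.ndarray:
    if x.size < window:
        raise InputError(f"signal too short for derivative window ({x.size} < {window})")
    return sps.savgol_filter(x, window_length=window, polyorder=polyorder,
                             deriv=deriv, delta=1.0 / fs)


def second_derivative(ppg: PPGSignal, window: int = 7, polyorder: int = 4) -> APGSignal:
    """Smoothed polynomial second differentiation (Savitzky-Golay).

    A local polynomial fit over ``window`` samples replaces raw double
    differencing, which would amplify quantization noise and bury the
    c/d/e waves.  The default quartic window of 7 samples at 100 Hz is
    accurate to well under 1% up to the ~10 Hz band where APG wave
    curvature lives.
    """
    if ppg.samples.size < 5:
        raise InputError("need at least 5 samples for a second derivative")
    apg = _savgol(ppg.samples, ppg.fs, 2, window, polyorder)
    return APGSignal(apg, ppg.fs, edge=window // 2)


def first_derivative(ppg: PPGSignal, window: int = 7, polyorder: int = 4) -> np.ndarray:
    """Savitzky-Golay first derivative (a.u./s), used for onset detection."""
    return _savgol(ppg.samples, ppg.fs, 1, window, polyorder)


def segment_beats(
    ppg: PPGSignal,
    apg: APGSignal,
    min_period: float = 0.3,
    max_period: float = 2.0,
    peak_height_frac: float = 0.5,
    refractory: float = 0.55,
    onset_search: float = 0.25,
) -> list[Beat]:
    """Segment a conditioned PPG into beats.

    The beat onset ("rise of the APG") is the foot of the pulse: the
    upward zero crossing of the PPG first derivative nearest before the
    a-wave maximum.  a-wave candidates are prominent APG maxima above
    ``peak_height_frac`` of the global maximum, at least ``refractory``
    seconds apart (within that distance only the taller peak survives,
    which suppresses e-waves).  Inter-onset intervals outside
    ``[min_period, max_period]`` seconds are not physiologic beats and
    are dropped; a flat or empty signal yields an empty list.
    """
    x = apg.samples
    if x.size == 0 or np.ptp(x) < 1e-12 or np.max(x) <= 0:
        return []
    peaks, _ = sps.find_peaks(
        x,
        height=peak_height_frac * float(np.max(x)),
        distance=max(1, int(round(refractory * apg.fs))),
    )
    if peaks.size == 0:
        return []
    d1 = first_derivative(ppg)
    back = int(round(onset_search * ppg.fs))
    onsets: list[int] = []
    for p in peaks:
        lo = max(0, p - back)
        seg = d1[lo : p + 1]
        # nearest upward zero crossing before the a-wave
        crossing = None
        for i in range(seg.size - 2, -1, -1):
            if seg[i] <= 0.0 < seg[i + 1]:
                frac = seg[i] / (seg[i] - seg[i + 1])
                crossing = lo + i + frac
                break
        if crossing is None:
            continue
        idx = int(round(crossing))
        if not onsets or idx > onsets[-1]:
            onsets.append(idx)
    beats = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        period = (b - a) / ppg.fs
        if min_period <= period <= max_period:
            beats.append(Beat(a, b, ppg.fs))
    return beats


def pulse_rate(beats: list[Beat], window: float = 60.0) -> float:
    """Pulse rate (bpm) from the beat count in the trailing window.

    Counts beat onsets in the half-open interval ``(t_last - window,
    t_last]`` where ``t_last`` is the last onset, and scales the count
    to 60 s.  Raises :class:`UndefinedPulseRateError` (distinguishable
    from a zero rate) when fewer than two beats fall in the window.
    """
    if window <= 0:
        raise InputError("window must be positive")
    onset_times = np.array([b.onset_time for b in beats])
    if onset_times.size == 0:
        raise UndefinedPulseRateError("no beats")
    t_last = onset_times[-1]
    n = int(np.sum(onset_times > t_last - window))
    if n < 2:
        raise UndefinedPulseRateError(f"only {n} beat(s) in the trailing {window} s")
    return 60.0 * n / window


# ---------------------------------------------------------------------------
# CSV dialect: optional "# fs=<Hz>" header, then "time_s,amplitude" rows.

def write_ppg_csv(path, ppg: PPGSignal) -> None:
    t = ppg.times
    with open(path, "w") as fh:
        fh.write(f"# fs={ppg.fs:g}\n")
        fh.write("time_s,amplitude\n")
        for ti, xi in zip(t, ppg.samples):
            fh.write(f"{ti:.4f},{xi:.10g}\n")


def read_ppg_csv(path, fs: float | None = None) -> PPGSignal:
    """Read the two-column PPG dialect; ``fs`` overrides a missing header."""
    header_fs = None
    rows = []
    opener = open(path) if not isinstance(path, io.TextIOBase) else path
    with opener as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fs=" in line:
                    header_fs = float(line.split("fs=")[1])
                continue
            if line.lower().startswith("time"):
                continue
            _, amp = line.split(",")
            rows.append(float(amp))
    rate = header_fs if header_fs is not None else fs
    if rate is None:
        raise InputError("no fs header in file and no fs override given")
    return PPGSignal(np.array(rows), rate)
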