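"""APG fiducial detection and the 20-feature vector for one measurement.

Per beat, the waves a-e are the acceleration waveform's alternating
extrema in chronological order: a is the first local maximum after the
pulse foot, b the first minimum after a, then c (max), d (min), e
(max).  The systolic and reflected components a-d are searched within
60% of the beat period; the diastolic e-wave may fall slightly later
and is searched to 75%.  A maximum that appears after b but beyond 42%
of the period is taken to be the diastolic e-wave with the reflected
c/d pair absent (flagged invalid) — when the dicrotic structure merges
c and d into an inflection we flag rather than invent a recovery.

Feature vector (per measurement window): the five wave heights, the
five times from the APG rise (the beat onset) to each wave, the ratios
b/a, c/a, d/a, e/a, the APG index (c + d - b)/a, the pulse rate, and
the questionnaire covariates height [m], weight [kg], age [yr] and sex
(male 0 / female 1).  Per-beat values are aggregated by the median over
fully valid beats, which is robust to occasional missed detections.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (DegenerateBeatError, InputError, NoFeaturesError,
                     NoFiducialsError)
from .preprocess import (APGSignal, Beat, PPGSignal, bandpass, pulse_rate,
                         second_derivative, segment_beats)
from .synth import WAVES

__all__ = [
    "APGFiducials",
    "FeatureVector",
    "FEATURE_NAMES",
    "STATIC_FEATURES",
    "detect_fiducials",
    "apg_index",
    "compute_features",
    "extract_features",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
]

#: Canonical feature order (the measurement table's column order).
FEATURE_NAMES = (
    "a", "b", "c", "d", "e",
    "Ta", "Tb", "Tc", "Td", "Te",
    "b/a", "c/a", "d/a", "e/a", "APG_index",
    "PR", "height", "weight", "age", "sex",
)

#: Questionnaire ("static") features, the ablation set.
STATIC_FEATURES = ("height", "weight", "age", "sex")


@dataclass
class APGFiducials:
    """Times (s from the APG rise) and heights (a.u./s^2) of a-e waves."""

    times: dict = field(default_factory=dict)
    heights: dict = field(default_factory=dict)
    valid: dict = field(default_factory=lambda: {w: False for w in WAVES})

    @property
    def all_valid(self) -> bool:
        return all(self.valid.get(w, False) for w in WAVES)


@dataclass
class FeatureVector:
    values: dict

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES})


def _refine(x: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum location/height by a 3-point parabola."""
    if i <= 0 or i >= x.size - 1:
        return float(i), float(x[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    height = y1 - 0.25 * (y0 - y2) * delta
    return i + delta, float(height)


def detect_fiducials(
    apg_beat: np.ndarray,
    fs: float,
    period: float | None = None,
    prominence_frac: float = 0.02,
    systolic_horizon: float = 0.6,
    e_horizon: float = 0.75,
    e_boundary: float = 0.42,
) -> APGFiducials:
    """Locate the a-e waves in one beat's acceleration samples.

    ``apg_beat`` starts at the beat onset (the APG rise).  Local
    extrema need a prominence of ``prominence_frac`` of the beat's APG
    peak-to-peak range, which suppresses noise ripples.  Waves that
    cannot be located are flagged invalid; a beat with no a-wave at all
    raises :class:`NoFiducialsError`.
    """
    x = np.asarray(apg_beat, dtype=float)
    if x.size < 5:
        raise NoFiducialsError("beat too short")
    if period is None:
        period = x.size / fs
    rng_ptp = float(np.ptp(x))
    if rng_ptp < 1e-12:
        raise NoFiducialsError("flat beat")
    prom = prominence_frac * rng_ptp
    maxima, _ = sps.find_peaks(x, prominence=prom)
    minima, _ = sps.find_peaks(-x, prominence=prom)
    extrema = sorted([(i, +1) for i in maxima] + [(i, -1) for i in minima])

    lim_sys = systolic_horizon * period * fs
    lim_e = e_horizon * period * fs
    lim_cd = e_boundary * period * fs

    fid = APGFiducials()

    def record(wave: str, idx: int) -> None:
        pos, height = _refine(x, idx)
        fid.times[wave] = pos / fs
        fid.heights[wave] = height
        fid.valid[wave] = True

    a_idx = next((i for i, s in extrema if s > 0 and i <= lim_sys), None)
    if a_idx is None or x[a_idx] <= 0:
        raise NoFiducialsError("no a-wave")
    record("a", a_idx)
    rest = [(i, s) for i, s in extrema if i > a_idx]

    b_idx = next((i for i, s in rest if s < 0 and i <= lim_sys), None)
    if b_idx is None or x[b_idx] >= 0:
        return fid
    record("b", b_idx)
    rest = [(i, s) for i, s in rest if i > b_idx]

    nxt_max = next((i for i, s in rest if s > 0 and i <= lim_e), None)
    if nxt_max is None:
        return fid
    if nxt_max > lim_cd:
        # too late to be the reflected wave: this is the diastolic e-wave
        record("e", nxt_max)
        return fid
    record("c", nxt_max)
    rest = [(i, s) for i, s in rest if i > nxt_max]

    d_idx = next((i for i, s in rest if s < 0 and i <= lim_sys), None)
    if d_idx is None:
        return fid
    record("d", d_idx)
    rest = [(i, s) for i, s in rest if i > d_idx]

    e_idx = next((i for i, s in rest if s > 0 and i <= lim_e), None)
    if e_idx is not None:
        record("e", e_idx)
    return fid


def apg_index(a: float, b: float, c: float, d: float) -> float:
    """The composite vascular index (c + d - b) / a."""
    if a == 0:
        raise DegenerateBeatError("a-wave height is zero")
    return (c + d - b) / a


def compute_features(
    beats_fiducials: list[APGFiducials],
    pr: float,
    questionnaire: dict,
) -> FeatureVector:
    """Aggregate per-beat fiducials into the measurement feature vector.

    Uses the median over fully valid beats; ratios and the APG index
    are computed from the aggregated heights.  Raises
    :class:`NoFeaturesError` when no beat has all five waves.
    """
    valid = [f for f in beats_fiducials if f.all_valid]
    if not valid:
        raise NoFeaturesError("no beat with a complete set of fiducials")
    agg_h = {w: float(np.median([f.heights[w] for f in valid])) for w in WAVES}
    agg_t = {w: float(np.median([f.times[w] for f in valid])) for w in WAVES}
    a = agg_h["a"]
    if a == 0:
        raise DegenerateBeatError("aggregated a-wave height is zero")
    values = {
        **{w: agg_h[w] for w in WAVES},
        **{f"T{w}": agg_t[w] for w in WAVES},
        "b/a": agg_h["b"] / a,
        "c/a": agg_h["c"] / a,
        "d/a": agg_h["d"] / a,
        "e/a": agg_h["e"] / a,
        "APG_index": apg_index(a, agg_h["b"], agg_h["c"], agg_h["d"]),
        "PR": float(pr),
        "height": float(questionnaire["height"]),
        "weight": float(questionnaire["weight"]),
        "age": float(questionnaire["age"]),
        "sex": int(questionnaire["sex"]),
    }
    return FeatureVector(values)


def extract_features(
    ppg: PPGSignal,
    questionnaire: dict,
    band: tuple | None = (0.3, 18.0),
    pr_window: float | None = None,
) -> FeatureVector:
    """Full per-measurement pipeline: condition, segment, detect, aggregate.

    ``band=None`` skips filtering (already-conditioned input).  The
    pulse-rate window defaults to the trailing 60 s, shortened to the
    recording length for short measurements.
    """
    cond = bandpass(ppg, *band) if band is not None else ppg
    apg = second_derivative(cond)
    beats = segment_beats(cond, apg)
    if not beats:
        raise NoFeaturesError("no beats segmented")
    fids = []
    for beat in beats:
        seg = apg.samples[beat.onset:beat.end]
        try:
            fids.append(detect_fiducials(seg, ppg.fs, period=beat.period))
        except NoFiducialsError:
            continue
    if pr_window is None:
        pr_window = min(60.0, ppg.duration)
    pr = pulse_rate(beats, window=pr_window)
    return compute_features(fids, pr, questionnaire)


def features_to_frame(rows: list[tuple]) -> pd.DataFrame:
    """Build the measurement table: one row per (subject_id, timestamp, fv)."""
    records = []
    for subject_id, timestamp, fv in rows:
        rec = {"subject_id": subject_id, "timestamp": timestamp}
        rec.update({k: fv.values[k] for k in FEATURE_NAMES})
        records.append(rec)
    return pd.DataFrame(records, columns=["subject_id", "timestamp", *FEATURE_NAMES])


def write_features_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
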