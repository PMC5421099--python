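"""Synthetic wrist-PPG cohorts with analytic fiducial ground truth.

The generator provides the statistical structure the estimator assumes:

* demographics (height, weight, age, sex) with realistic covariate
  effects on systolic blood pressure,
* per-subject beat morphology whose APG wave heights are an *affine*
  function of a morphology-level SBP (a rises, b and e fall as SBP
  rises, with mild age effects on the reflected/diastolic waves), so a
  linear feature->SBP model is recoverable by construction,
* 100 Hz PPG recordings whose acceleration waveform has exactly five
  alternating extrema per beat (a, b, c, d, e), with the extremum times
  and heights of the *analytic* second derivative recorded as ground
  truth for detector tests,
* PTT series affine-decreasing in SBP (the conventional baseline's
  input), and 24-h BP series realizing each nocturnal dipping pattern.

Beat template
-------------
Each beat of duration ``T`` is built directly in curvature space: the
analytic APG is a sum of five Gaussian bumps with alternating signs at
fixed fractions of the beat, plus two wide late-diastolic compensation
bumps whose amplitudes are solved so that the twice-integrated waveform
is continuous and periodic across beats with a prescribed (slightly
negative) boundary slope.  The PPG is the closed-form double integral
of that curvature, so the sampled waveform, its analytic second
derivative, and the recorded fiducials are mutually exact.  Because
bump centers and widths scale with ``T``, extremum heights are an exact
linear map of the component amplitudes, independent of heart period.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from .errors import ConfigurationError, InputError
from .preprocess import PPGSignal

__all__ = [
    "WAVES",
    "BeatMorphology",
    "SyntheticSubject",
    "GroundTruth",
    "generate_population",
    "population_frame",
    "write_population_csv",
    "read_population_csv",
    "synthesize_ppg",
    "synthesize_ptt",
    "synthesize_bp_series",
    "morphology_to_sbp",
    "SBP_REF",
    "A_WAVE_REF",
    "A_WAVE_SLOPE",
]

WAVES = ("a", "b", "c", "d", "e")
_SQRT2PI = math.sqrt(2.0 * math.pi)

# Affine morphology <-> SBP anchor: a-wave height at the reference SBP and
# its slope per mmHg.  These two constants define the generator's own
# linear SBP predictor (see morphology_to_sbp).
SBP_REF = 120.0
A_WAVE_REF = 40.0
A_WAVE_SLOPE = 0.28


@dataclass
class BeatMorphology:
    """Per-beat wave-component parameters in curvature (APG) space.

    ``amplitudes`` are the target APG heights (a.u./s^2) of the five
    waves; ``center_fracs`` and ``width_frac`` place and size the
    Gaussian components as fractions of the heart period, so the beat
    shape is heart-period invariant.
    """

    amplitudes: dict = field(default_factory=lambda: {
        "a": 40.0, "b": -36.0, "c": 12.0, "d": -14.0, "e": 20.0})
    center_fracs: tuple = (0.11, 0.21, 0.31, 0.41, 0.51)
    width_frac: float = 0.040
    heart_period: float = 0.90
    comp_center_fracs: tuple = (0.70, 0.86)
    comp_width_frac: float = 0.055
    boundary_slope_frac: float = -0.25

    def __post_init__(self):
        if not 0.4 <= self.heart_period <= 1.5:
            raise ConfigurationError(f"heart period {self.heart_period} outside [0.4, 1.5] s")
        if not all(x < y for x, y in zip(self.center_fracs, self.center_fracs[1:])):
            raise ConfigurationError("component centers must be strictly increasing")
        if self.center_fracs[-1] >= min(self.comp_center_fracs):
            raise ConfigurationError("compensation bumps must follow the e-wave")
        amp = self.amplitudes
        if not (amp["a"] > 0 and amp["b"] < 0 and amp["e"] > 0):
            raise ConfigurationError("need a > 0, b < 0, e > 0")
        # the reflected c/d pair may vanish (merged dicrotic structure)
        if not (amp["c"] >= 0 and amp["d"] <= 0):
            raise ConfigurationError("need c >= 0 and d <= 0")


class _BeatTemplate:
    """Closed-form beat: curvature = Gaussian mixture, PPG = its double integral."""

    def __init__(self, m: BeatMorphology):
        T = m.heart_period
        self.T = T
        mu = [f * T for f in m.center_fracs] + [f * T for f in m.comp_center_fracs]
        w = [m.width_frac * T] * 5 + [m.comp_width_frac * T] * 2
        amp = [m.amplitudes[k] for k in WAVES] + [0.0, 0.0]
        self.mu = np.array(mu)
        self.w = np.array(w)
        amp = np.array(amp)
        # Boundary slope of the PPG (a.u./s): a small negative late-diastolic
        # decay so the pulse foot is a clean upward zero crossing.
        self.v0 = m.boundary_slope_frac * amp[0] * self.w[0] * _SQRT2PI

        # Solve the two compensation amplitudes so that over one beat
        #   (C1)  integral APG = 0            -> PPG'(T) = PPG'(0) = v0
        #   (C2)  integral PPG' = 0           -> PPG(T) = PPG(0) = 0
        def I0(mu_, w_):
            return w_ * _SQRT2PI * (ndtr((T - mu_) / w_) - ndtr(-mu_ / w_))

        def I1(mu_, w_):  # integral of (T - t) * bump
            g = lambda t: math.exp(-((t - mu_) ** 2) / (2 * w_ ** 2))
            return (T - mu_) * I0(mu_, w_) + w_ ** 2 * (g(T) - g(0.0))

        i0 = np.array([I0(self.mu[j], self.w[j]) for j in range(7)])
        i1 = np.array([I1(self.mu[j], self.w[j]) for j in range(7)])
        A = np.array([[i0[5], i0[6]], [i1[5], i1[6]]])
        b = -np.array([amp[:5] @ i0[:5], self.v0 * T + amp[:5] @ i1[:5]])
        gamma = np.linalg.solve(A, b)
        amp[5], amp[6] = gamma
        self.amp = amp

    # -- analytic pieces ---------------------------------------------------
    def apg(self, t):
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - self.mu) / self.w
        return np.exp(-0.5 * z ** 2) @ self.amp

    def apg_prime(self, t):
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - self.mu) / self.w
        return (np.exp(-0.5 * z ** 2) * (-z / self.w)) @ self.amp

    def ppg_prime(self, t):
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - self.mu) / self.w
        z0 = -self.mu / self.w
        return self.v0 + ((ndtr(z) - ndtr(z0)) * (self.w * _SQRT2PI)) @ self.amp

    def ppg(self, t):
        t = np.asarray(t, dtype=float)
        z = (t[..., None] - self.mu) / self.w
        z0 = -self.mu / self.w

        def I(zz):  # integral of the standard normal CDF
            return zz * ndtr(zz) + np.exp(-0.5 * zz ** 2) / _SQRT2PI

        inner = self.w * (I(z) - I(z0)) - t[..., None] * ndtr(z0)
        return self.v0 * t + (inner * (self.w * _SQRT2PI)) @ self.amp

    # -- ground truth ------------------------------------------------------
    def fiducials(self):
        """Extremum times/heights of the analytic APG, and the pulse foot.

        Returns (onset_time, times, heights): times are seconds from the
        *foot* (the upward zero crossing of the analytic PPG slope
        preceding the a-wave), matching the detector's time origin.
        """
        times = {}
        heights = {}
        for j, wave in enumerate(WAVES):
            if abs(self.amp[j]) < 1e-9:  # suppressed wave: no extremum exists
                continue
            half = self.w[j]
            lo, hi = self.mu[j] - 0.9 * half, self.mu[j] + 0.9 * half
            flo, fhi = self.apg_prime(lo), self.apg_prime(hi)
            if flo * fhi > 0:  # overlap pushed the extremum; widen bracket
                lo, hi = self.mu[j] - 2.0 * half, self.mu[j] + 2.0 * half
                flo, fhi = self.apg_prime(lo), self.apg_prime(hi)
            t_ext = brentq(lambda t: float(self.apg_prime(t)), lo, hi)
            times[wave] = t_ext
            heights[wave] = float(self.apg(t_ext))
        lo = self.mu[0] - 3.0 * self.w[0]
        lo = max(lo, 1e-6)
        onset = brentq(lambda t: float(self.ppg_prime(t)), lo, self.mu[0])
        rel = {k: times[k] - onset for k in times}
        return onset, rel, heights


@dataclass
class SyntheticSubject:
    """One simulated subject: questionnaire covariates, true BP, morphology."""

    subject_id: str
    height: float  # m
    weight: float  # kg
    age: float     # yr
    sex: int       # male 0, female 1
    true_sbp: float  # mmHg
    true_dbp: float  # mmHg
    morphology: BeatMorphology
    morph_sbp: float = None  # SBP value the waveform actually encodes

    def __post_init__(self):
        if not 1.2 <= self.height <= 2.1:
            raise ConfigurationError(f"height {self.height} outside [1.2, 2.1] m")
        if not 35 <= self.weight <= 150:
            raise ConfigurationError(f"weight {self.weight} outside [35, 150] kg")
        if not 18 <= self.age <= 95:
            raise ConfigurationError(f"age {self.age} outside [18, 95]")
        if self.sex not in (0, 1):
            raise ConfigurationError("sex must be 0 (male) or 1 (female)")
        if not 80 <= self.true_sbp <= 200:
            raise ConfigurationError(f"SBP {self.true_sbp} outside [80, 200]")
        if not self.true_dbp < self.true_sbp:
            raise ConfigurationError("DBP must be below SBP")

    @property
    def questionnaire(self) -> dict:
        return {"height": self.height, "weight": self.weight,
                "age": self.age, "sex": self.sex}


@dataclass
class GroundTruth:
    """Oracle sidecar for one recording: onsets and per-beat fiducials."""

    beat_onsets: np.ndarray          # sample indices of the pulse foot
    fiducial_times: dict             # wave -> array of s-from-onset, per beat
    fiducial_heights: dict           # wave -> array of a.u./s^2, per beat
    fs: float
    heart_period: float

    @property
    def n_beats(self) -> int:
        return int(self.beat_onsets.size)

    def to_json(self, path) -> None:
        doc = {
            "fs": self.fs,
            "heart_period": self.heart_period,
            "beat_onsets": [int(i) for i in self.beat_onsets],
            "fiducial_times": {k: list(map(float, v)) for k, v in self.fiducial_times.items()},
            "fiducial_heights": {k: list(map(float, v)) for k, v in self.fiducial_heights.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            beat_onsets=np.array(doc["beat_onsets"], dtype=int),
            fiducial_times={k: np.array(v) for k, v in doc["fiducial_times"].items()},
            fiducial_heights={k: np.array(v) for k, v in doc["fiducial_heights"].items()},
            fs=doc["fs"],
            heart_period=doc["heart_period"],
        )


_DEFAULT_RANGES = {"age": (25.0, 80.0), "height": (1.45, 1.98), "weight": (45.0, 115.0)}


def _morphology_for(sbp: float, age: float, noise: np.ndarray,
                    heart_period: float) -> BeatMorphology:
    ds = sbp - SBP_REF
    da = age - 50.0
    amp = {
        "a": A_WAVE_REF + A_WAVE_SLOPE * ds + noise[0],
        "b": -36.0 - 0.22 * ds + 0.10 * da + noise[1],
        "c": 12.0 - 0.06 * da + noise[2],
        "d": -14.0 - 0.04 * ds - 0.04 * da + noise[3],
        "e": 20.0 - 0.12 * ds - 0.05 * da + noise[4],
    }
    # keep alternating signs under extreme draws
    amp["a"] = max(amp["a"], 8.0)
    amp["b"] = min(amp["b"], -6.0)
    amp["c"] = max(amp["c"], 2.0)
    amp["d"] = min(amp["d"], -2.0)
    # the diastolic wave never rivals the systolic driving wave
    amp["e"] = min(max(amp["e"], 3.0), 0.75 * amp["a"])
    shift = 2.0e-4 * da
    fracs = (0.11, 0.21, 0.31 + shift, 0.41 + shift, 0.51 + shift)
    return BeatMorphology(amplitudes=amp, center_fracs=fracs, heart_period=heart_period)


def morphology_to_sbp(morphology: BeatMorphology) -> float:
    """The generator's own linear SBP predictor (inverts the a-wave map).

    With morphology noise and BP-level noise at zero this recovers the
    subject's SBP exactly; it is the construction that guarantees a
    linear feature->SBP model exists for the estimator to find.
    """
    return SBP_REF + (morphology.amplitudes["a"] - A_WAVE_REF) / A_WAVE_SLOPE


def generate_population(
    n: int,
    seed: int,
    demographic_ranges: dict | None = None,
    *,
    covariate_effect_scale: float = 1.0,
    individual_sd: float = 12.0,
    bp_noise_sd: float = 8.0,
    morph_noise_sd: float = 0.5,
) -> list[SyntheticSubject]:
    """Draw ``n`` subjects with BP-linked beat morphology.

    SBP is built from covariates (age, weight, sex; scaled by
    ``covariate_effect_scale``) plus N(0, ``individual_sd``) individual
    variation.  The waveform encodes ``morph_sbp = true_sbp +
    N(0, bp_noise_sd)`` — the BP-level noise is the irreducible error of
    any waveform-based estimator — and each wave amplitude additionally
    gets N(0, ``morph_noise_sd``) of its own.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    ranges = dict(_DEFAULT_RANGES)
    if demographic_ranges:
        ranges.update(demographic_ranges)
    for key, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ConfigurationError(f"degenerate range for {key}: ({lo}, {hi})")
    if not (1.2 <= ranges["height"][0] and ranges["height"][1] <= 2.1):
        raise ConfigurationError("height range outside [1.2, 2.1] m")
    if not (35 <= ranges["weight"][0] and ranges["weight"][1] <= 150):
        raise ConfigurationError("weight range outside [35, 150] kg")
    if not (18 <= ranges["age"][0] and ranges["age"][1] <= 95):
        raise ConfigurationError("age range outside [18, 95]")

    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        age = float(rng.uniform(*ranges["age"]))
        sex = int(rng.integers(0, 2))
        height = float(np.clip(rng.normal(1.76 - 0.12 * sex, 0.07), *ranges["height"]))
        weight = float(np.clip(rng.normal(22.5 * height ** 2, 9.0), *ranges["weight"]))
        effect = covariate_effect_scale * (
            0.55 * (age - 50.0) + 0.30 * (weight - 70.0) - 5.0 * sex)
        sbp = float(np.clip(124.0 + effect + rng.normal(0, individual_sd), 80.0, 200.0))
        dbp = float(np.clip(0.55 * sbp + 10.0 + rng.normal(0, 4.0), 45.0, sbp - 15.0))
        morph_sbp = float(np.clip(sbp + rng.normal(0, bp_noise_sd), 80.0, 200.0))
        noise = rng.normal(0.0, morph_noise_sd, size=5) if morph_noise_sd > 0 else np.zeros(5)
        period = float(np.clip(rng.normal(0.88, 0.07), 0.72, 1.10))
        morph = _morphology_for(morph_sbp, age, noise, period)
        subjects.append(SyntheticSubject(
            subject_id=f"S{i:04d}", height=height, weight=weight, age=age,
            sex=sex, true_sbp=sbp, true_dbp=dbp, morphology=morph,
            morph_sbp=morph_sbp))
    return subjects


def population_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    """Tabulate a population: questionnaire fields, BP and wave amplitudes."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "height": s.height, "weight": s.weight,
               "age": s.age, "sex": s.sex, "true_sbp": s.true_sbp,
               "true_dbp": s.true_dbp, "heart_period": s.morphology.heart_period}
        for w in WAVES:
            row[f"amp_{w}"] = s.morphology.amplitudes[w]
        rows.append(row)
    return pd.DataFrame(rows)


def write_population_csv(path, subjects: list[SyntheticSubject]) -> None:
    population_frame(subjects).to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def synthesize_ppg(
    subject: SyntheticSubject,
    duration: float,
    fs: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[PPGSignal, GroundTruth]:
    """Render a recording of ``floor(duration * fs)`` samples plus its oracle.

    The ground truth lists every *complete* beat — one whose foot and the
    next beat's foot both fall inside the record; partial boundary beats
    carry no ground truth.  With ``noise_sd=0`` the analytic second
    derivative of the beat template has its extrema exactly at the
    recorded fiducial times.
    """
    T = subject.morphology.heart_period
    if duration < 3 * T:
        raise InputError(f"duration {duration}s is shorter than 3 heart periods ({3 * T:.2f}s)")
    n = int(math.floor(duration * fs))
    tpl = _BeatTemplate(subject.morphology)
    t = np.arange(n) / fs
    k = np.floor(t / T)
    tau = t - k * T
    x = tpl.ppg(tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)

    onset_rel, times_rel, heights = tpl.fiducials()
    n_starts = int(math.floor((n - 1) / fs / T)) + 1
    feet = np.round((np.arange(n_starts + 1) * T + onset_rel) * fs).astype(int)
    # A complete beat needs its own foot, the next beat's foot, *and* the
    # next beat's a-wave inside the record (with a few samples to spare
    # for the differentiator edge): a closing onset in the record's final
    # samples is not detectable without the systolic upstroke after it.
    margin = int(round(times_rel["a"] * fs)) + 4
    complete = feet[:-1][(feet[:-1] <= n - 1) & (feet[1:] + margin <= n - 1)]
    nb = complete.size
    gt = GroundTruth(
        beat_onsets=complete,
        fiducial_times={w: np.full(nb, times_rel[w]) for w in times_rel},
        fiducial_heights={w: np.full(nb, heights[w]) for w in times_rel},
        fs=fs,
        heart_period=T,
    )
    return PPGSignal(x, fs), gt


def synthesize_ptt(
    subject: SyntheticSubject,
    sbp_per_minute,
    noise_sd: float = 8.0,
    seed: int | None = None,
    p0: float = 350.0,
    p1: float = 1.0,
) -> np.ndarray:
    """Pulse transit time (ms) affine-decreasing in SBP plus Gaussian noise.

    ``PTT = p0 - p1 * SBP + N(0, noise_sd)``; with ``noise_sd=0`` the
    correlation with SBP is exactly -1.  Magnitudes follow the typical
    order of the PTT literature and are fully configurable.
    """
    sbp = np.asarray(sbp_per_minute, dtype=float)
    if sbp.size == 0:
        raise InputError("SBP series is empty")
    ptt = p0 - p1 * sbp
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ptt = ptt + rng.normal(0.0, noise_sd, size=sbp.shape)
    return ptt


_DECLINE_RANGES = {
    "dipper": (0.12, 0.18),
    "nondipper": (0.03, 0.08),
    "extreme": (0.22, 0.28),
    "riser": (-0.08, -0.03),
}


def synthesize_bp_series(
    pattern: str,
    day_mean: float,
    seed: int | None = None,
    *,
    start: str = "2024-03-04",  # a Monday
    days: int = 1,
    cadence_min: int = 30,
    noise_sd: float = 2.0,
    dbp_ratio: float = 0.65,
):
    """A 24-h (or multi-day) BP series realizing a dipping pattern.

    One reading per ``cadence_min`` minutes.  The nocturnal decline is
    drawn inside the pattern's band with margin from the 10%/20%
    boundaries, and reading noise is re-centred within each day/night
    window so the window means hit the construction targets exactly —
    the classifier applied to the output returns the requested pattern.
    """
    from .bpv import BPSeries  # local import to avoid a cycle

    if pattern not in _DECLINE_RANGES:
        raise ConfigurationError(
            f"unknown pattern {pattern!r}; expected one of {sorted(_DECLINE_RANGES)}")
    if not 80 <= day_mean <= 200:
        raise InputError(f"day mean {day_mean} outside [80, 200] mmHg")
    rng = np.random.default_rng(seed)
    decline = float(rng.uniform(*_DECLINE_RANGES[pattern]))
    night_mean = day_mean * (1.0 - decline)
    dbp_day = dbp_ratio * day_mean
    dbp_night = dbp_day * (1.0 - decline)

    times = pd.date_range(start=start, periods=days * (24 * 60 // cadence_min),
                          freq=f"{cadence_min}min")
    hours = times.hour
    is_day = (hours >= 6) & (hours < 22)
    sbp = np.where(is_day, day_mean, night_mean).astype(float)
    dbp = np.where(is_day, dbp_day, dbp_night).astype(float)
    for mask in (is_day, ~is_day):
        e_s = rng.normal(0, noise_sd, size=int(mask.sum()))
        e_d = rng.normal(0, noise_sd / 2, size=int(mask.sum()))
        sbp[mask] += e_s - e_s.mean()
        dbp[mask] += e_d - e_d.mean()
    frame = pd.DataFrame({"time": times, "sbp": sbp, "dbp": dbp})
    return BPSeries(frame)
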