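# Methods

This note documents the models, numerical choices and study conditions
behind `apgbp`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do
not demonstrate.

## 1. Signal model and conditioning

A PPG record is a uniformly sampled scalar series (default 100 Hz, the
rate of wrist-worn optical sensors). Conditioning is a zero-phase
4th-order Butterworth band-pass, default **0.3–18 Hz**. Both corners
were chosen against the analytic waveform oracle (§5): a 0.5 Hz high-
pass corner visibly tilts the slow pre-systolic baseline and shifts the
pulse-foot zero crossing by up to one sample, while a 10 Hz low-pass
clips the curvature content of the APG waves and biases their heights
by ~6%; 0.3–18 Hz keeps both errors well inside the detector's
tolerance. The filter removes DC entirely.

The **APG** is computed by Savitzky–Golay differentiation: a local
polynomial of order 4 over a 7-sample window (70 ms at 100 Hz),
evaluated for its second derivative. Raw double-differencing amplifies
quantization noise and buries the small c/d/e waves; conversely a
*quadratic* local fit over the same window attenuates curvature in the
5–8 Hz band by 8–19%, which is where APG wave structure lives. The
quartic window is 4th-order accurate (amplitude error < 0.1% below
10 Hz) while still smoothing single-sample noise. Window length and
order are parameters. Samples inside the half-window at each record
edge are flagged invalid, not extrapolated.

## 2. Beat segmentation and fiducial detection

The beat onset ("rise of the APG") is the **pulse foot**: the upward
zero crossing of the PPG first derivative nearest before the a-wave
maximum, searched up to 250 ms back. a-wave candidates are APG maxima
above 50% of the record maximum with a 0.55 s refractory interval
(within it only the taller peak survives, which suppresses e-waves that
approach the a-wave in height). The refractory assumes a resting pulse
below ≈ 110 bpm — appropriate for seated measurements; it is a
parameter. Inter-onset intervals outside 0.3–2.0 s are discarded as
non-physiologic, which also prevents beats from spanning flat gaps or
artifacts. This interval filter is the package's minimal stand-in for
measurement quality control; stricter rules can be layered on top.

Within a beat the waves are assigned chronologically: a = first local
maximum, b = first minimum after a, then c (max), d (min), e (max).
a–d are searched within 60% of the beat period, e up to 75% (the
diastolic wave may fall slightly later). Local extrema require a
prominence of 2% of the beat's APG peak-to-peak range. A maximum
following b but **later than 42% of the period** is taken to be the
diastolic e-wave with the reflected c/d pair absent and c, d are
flagged invalid — when the dicrotic structure merges c and d into an
inflection we flag rather than invent a recovery. Extremum times and
heights are refined by a three-point parabola, giving sub-sample
resolution. Per-window features aggregate per-beat values by the
median over beats with all five waves valid (robust to occasional
missed detections); ratios and the APG index are computed from the
aggregated heights. Pulse rate is the onset count in the trailing
60 s window scaled to one minute (shortened to the record length for
short measurements); fewer than two beats raises a distinguishable
undefined-rate signal rather than returning zero.

## 3. Regression, baseline and evaluation

The SBP model is ordinary least squares on the selected features,
`y = u₀ + Σ uᵢxᵢ`. **Stepwise selection** is bidirectional: each
iteration adds the candidate with the smallest partial-t p-value if it
is below α_in = 0.05, then removes the worst included feature if its
p-value exceeds α_out = 0.10 (classical thresholds; α_in ≤ α_out
avoids cycling, and revisiting a previously seen feature set stops the
loop). When the fit becomes numerically perfect (residual sum of
squares below 10⁻¹² of the target's variance) forward entry stops,
which makes noiseless fixtures well-defined. A BIC mode
(add/remove whichever single change most improves the Gaussian BIC) is
provided and is the mode checked against exhaustive best-subset search
in the tests. The solver is `numpy.linalg.lstsq` with classical
normal-theory standard errors; the test suite cross-checks
coefficients and p-values against statsmodels and a closed-form
normal-equations oracle. Rank-deficient designs raise an error naming
the collinear columns (pivoted QR).

The **PTT baseline** regresses BP deviation on PTT deviation (simple
least squares), both taken from the first paired sample — the
reference reading, whose deviations are zero by construction — and
predicts absolute pressure by adding the reference back.

Error convention throughout: **error = estimated − measured**; reports
give the Pearson r between measured and estimated pressure, the mean
error, and the sample SD of errors (n−1), plus a per-subject
breakdown. Evaluation supports both disjoint train/test and
leave-one-out cross-validation; in LOOCV the selection itself is
re-run in every fold. The machinery is target-agnostic (the same code
fits diastolic pressure), with systolic pressure as the default.

## 4. BPV analytics

Daytime is the local-clock window [06:00, 22:00), nighttime the
complement; a reading at exactly 22:00 is nocturnal. The nocturnal
decline is 100·(day − night)/day of mean SBP and maps to riser (< 0),
nondipper ([0, 10)), dipper ([10, 20)) and extreme-dipper (≥ 20). The
verbal clinical definitions overlap at exactly 10% and 20%; the
half-open intervals resolve the boundary upward (10% → dipper,
20% → extreme-dipper) so exactly one label applies to any input. The
diastolic decline is computed and reported but the label follows SBP.
Histograms use half-open, lower-edge-inclusive bins; weekly statistics
pool by weekday, Monday first. BMI and a configurable
calories-per-step factor are exposed as helpers. Timestamps are naive
local clock time; no daylight-saving handling is attempted.

## 5. Synthetic-data generator

The generator provides the statistical structure the estimator
assumes, with exact oracles.

**Beat template.** Each beat of duration T is defined directly in
curvature space: the analytic APG is five Gaussian bumps with
alternating signs at fixed fractions (0.11, 0.21, 0.31, 0.41, 0.51) of
T, width 0.04 T, plus two wide late-diastolic compensation bumps
(centers 0.70 T and 0.86 T) whose amplitudes are solved from two linear
constraints so that the twice-integrated waveform is continuous and
periodic with a prescribed small negative boundary slope (the
late-diastolic decay that makes the pulse foot a clean zero crossing).
The PPG is the closed-form double integral, so the sampled waveform and
its analytic second derivative are mutually exact. Ground-truth
fiducials are the extrema of the analytic APG located by root-finding
on its derivative; the ground-truth onset is the analytic foot. Because
centers and widths scale with T, realized wave heights are an exact
linear map of the component amplitudes independent of heart period —
the property that makes a linear feature → SBP model exactly
recoverable. A beat is *complete* (and carries ground truth) when its
foot, the next foot, and the next beat's a-wave all lie inside the
record; boundary beats carry no ground truth because their closing
onset cannot be detected without the upstroke that follows it.

**Morphology ↔ SBP map.** Wave amplitudes (a.u./s², at the reference
SBP 120 mmHg and age 50): a = 40 + 0.28·ΔSBP; b = −36 − 0.22·ΔSBP +
0.10·Δage; c = 12 − 0.06·Δage; d = −14 − 0.04·ΔSBP − 0.04·Δage;
e = 20 − 0.12·ΔSBP − 0.05·Δage — a rises while b and e fall with
pressure, and the age terms move the ratio features the way vascular
ageing does. Clamps keep the alternating sign structure under extreme
draws, and e is capped at 0.75·a (the diastolic wave never rivals the
systolic driving wave; without the cap, low-pressure draws make e ≈ a
and segmentation ambiguous). `morphology_to_sbp` inverts the a-wave
line and is the generator's own linear predictor.

**Cohort model.** Age ~ U(25, 80); sex Bernoulli(½); height and weight
from sex- and height-linked normals within physiologic ranges. SBP =
124 + 0.55·(age−50) + 0.30·(weight−70) − 5·sex + N(0, 12) mmHg,
clipped to [80, 200]; DBP follows SBP with noise. The waveform encodes
`morph_sbp = SBP + N(0, σ_BP)` with σ_BP = 8 mmHg by default — this
BP-level noise is the irreducible error of any waveform-based
estimator, standing in for cuff-vs-waveform decoupling — and each wave
amplitude adds N(0, 0.5) of its own. Heart period ~ N(0.88, 0.07) s
clipped to [0.72, 1.10]. PTT is affine-decreasing in SBP
(350 ms − 1 ms/mmHg) plus Gaussian noise; magnitudes follow the order
of the PTT literature and are configurable, never asserted as measured
values. 24-h BP series draw a nocturnal decline inside each pattern's
band with margin from the 10%/20% boundaries and re-center the reading
noise within each day/night window, so the construction targets are
exact.

**What the generator does not emulate:** motion artifacts, baseline
wander, arrhythmia, beat-to-beat morphology variability, hemodynamic
(Windkessel-type) coupling, or an ECG channel (PTT is generated
directly). Passing tests therefore demonstrate correctness of the
pipeline's mechanics and its statistical behaviour under the stated
model — not performance on real wrist recordings, where detection
robustness and the strength of the feature–pressure relation are the
open questions.

## 6. Study conditions in tests and the acceptance script

Problem sizes were chosen so the full suite and the acceptance script
each run in minutes on one CPU while keeping every check statistically
comfortable:

* fiducial oracle: 50 noiseless recordings of 15 s (≈ 850 beats);
  tolerances ±10 ms on wave times, 5% on heights, ±20 ms on onsets;
* end-to-end recovery: n = 600 subjects (tests) / 300 (script), 12 s
  recordings, σ_BP = 5 mmHg: LOOCV must land in the irreducible band
  (sd of errors 4.5–6.5 mmHg, r ≥ 0.85, |mean error| ≤ 1 mmHg); the
  noiseless variant must reach r ≥ 0.999;
* stepwise-vs-PTT ordering: 50 replicates (tests) / 20 (script) of 40
  subjects with PTT noise 40 ms, where the stepwise model must outrank
  the baseline in ≥ 95% of replicates;
* covariate ablation: a cohort with strong demographic effects
  (effect scale 1.5) and σ_BP = 12 mmHg, where the questionnaire
  features carry non-redundant signal, so removing them must lower r.
  With σ_BP = 5 and a near-noiseless waveform the covariates are
  mathematically redundant (the waveform already encodes the pressure
  they predict) and the ordering is not identifiable — the
  zero-effect control asserts exactly that indistinguishability;
* dipping closure: the classifier must return the requested pattern
  for all four patterns across 100 seeds (tests) / 50 (script).

All randomness flows from explicit seeds; generators are deterministic
given a seed, and the CLI writes byte-identical outputs for repeated
seeded runs.

## 7. Known limitations

* The e-wave/c-wave disambiguation (the 42%-of-period boundary) is a
  heuristic tuned to typical adult wave timing; pathological waveforms
  could mislabel a late reflected wave as diastolic.
* The stepwise engine's p-values are classical normal-theory values;
  no post-selection inference correction is applied (selection
  validity is assessed empirically, by LOOCV).
* The outbox guarantees at-least-once delivery and per-drain insertion
  order; across drains, a record that fails and is retried later can
  be delivered after records enqueued behind it.
* No regularized or nonlinear models, and no recalibration schemes:
  the method's point is calibration-free absolute estimation.
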