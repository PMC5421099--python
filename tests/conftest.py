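import numpy as np
import pandas as pd
import pytest

from apgbp import features as ft
from apgbp import synth


def build_feature_frame(subjects, duration=12.0, noise_sd=0.0, seed=0):
    """Run the full waveform -> feature pipeline over a cohort."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        ppg, _ = synth.synthesize_ppg(s, duration=duration, noise_sd=noise_sd,
                                      seed=int(rng.integers(2 ** 31)))
        fv = ft.extract_features(ppg, s.questionnaire)
        row = {k: fv.values[k] for k in ft.FEATURE_NAMES}
        row["sbp"] = s.true_sbp
        row["subject_id"] = s.subject_id
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort600_features():
    """n=600 cohort at 5 mmHg BP-level noise, full pipeline features.

    Shared by the end-to-end recovery and ablation tests (expensive)."""
    subjects = synth.generate_population(600, seed=42, bp_noise_sd=5.0,
                                         morph_noise_sd=0.5)
    frame = build_feature_frame(subjects, duration=12.0)
    return subjects, frame


@pytest.fixture(scope="session")
def ablation_cohort_features():
    """Cohort where questionnaire covariates carry real signal: strong
    demographic effects on SBP and a noisier waveform encoding, so the
    static features are informative rather than redundant."""
    subjects = synth.generate_population(600, seed=88, bp_noise_sd=12.0,
                                         morph_noise_sd=0.5,
                                         covariate_effect_scale=1.5)
    return build_feature_frame(subjects, duration=12.0)


@pytest.fixture()
def noiseless_subject():
    return synth.generate_population(1, seed=3, bp_noise_sd=0,
                                     morph_noise_sd=0)[0]
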