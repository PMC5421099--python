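"""Exception types shared across the toolkit."""


class ApgbpError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ApgbpError, ValueError):
    """Invalid generator or pipeline configuration (e.g. degenerate ranges)."""


class InputError(ApgbpError, ValueError):
    """Invalid input data (too short, wrong band, empty series, ...)."""


class NoFiducialsError(ApgbpError):
    """No a-wave could be located in a beat's acceleration waveform."""


class NoFeaturesError(ApgbpError):
    """No beat in the measurement window had a complete set of valid waves."""


class DegenerateBeatError(ApgbpError, ZeroDivisionError):
    """Ratio features undefined because the a-wave height is zero."""


class UndefinedPulseRateError(ApgbpError):
    """Fewer than two beats in the pulse-rate window."""


class SingularFitError(ApgbpError, ValueError):
    """Rank-deficient regression design. Carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class MissingFeatureError(ApgbpError, KeyError):
    """A fitted model was asked to predict without one of its features."""

    def __init__(self, name):
        self.name = name
        super().__init__(f"feature {name!r} required by the model is missing")


class DegenerateBaselineError(ApgbpError, ValueError):
    """PTT deviations have zero variance; the baseline slope is undefined."""


class FoldFitError(ApgbpError):
    """A cross-validation fold failed to fit. Names the fold."""

    def __init__(self, fold, cause):
        self.fold = fold
        super().__init__(f"fit failed in LOOCV fold {fold}: {cause}")


class InsufficientCoverageError(ApgbpError, ValueError):
    """A day/night window contains no readings. Names the window."""

    def __init__(self, window):
        self.window = window
        super().__init__(f"no readings in the {window} window")


class SchemaError(ApgbpError, ValueError):
    """A life-log record violates the recording schema."""
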