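"""Exception types shared across the package."""


class TissueCorrError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(TissueCorrError, ValueError):
    """A configuration value violates its constraints."""


class CalibrationError(TissueCorrError, RuntimeError):
    """Two-channel calibration could not be fitted (e.g. fully saturated input)."""


class DegenerateHullError(TissueCorrError, ValueError):
    """Convex-hull based size bounds are undefined (N <= N_ch)."""


class DegenerateDesignError(TissueCorrError, ValueError):
    """Regression design has no variation in the predictor."""


class InsufficientDataError(TissueCorrError, ValueError):
    """Too few observations to run the requested estimator."""


class NonIdentifiableError(TissueCorrError, ValueError):
    """Likelihood has no interior maximiser with the given data."""
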