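"""Exception hierarchy.

Each class maps to a distinct CLI exit code so that shell callers can
distinguish configuration mistakes from data problems from numerical
failures.
"""


class SIECVError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(SIECVError):
    """Invalid run configuration (unknown keys, out-of-range values)."""

    exit_code = 2


class DataValidationError(SIECVError):
    """Input data violates a structural contract (non-binary outcome, ...)."""

    exit_code = 3


class EstimationError(SIECVError):
    """A model fit or meta-analysis could not be completed."""

    exit_code = 4
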