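"""Exception hierarchy for the QFA screen pipeline."""


class QFAError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(QFAError, ValueError):
    """A growth-model parameter is non-finite or out of range."""


class InsufficientDataError(QFAError, ValueError):
    """A culture has too few observations to fit (fewer than 4)."""


class ConfigurationError(QFAError, ValueError):
    """A simulation or run configuration violates its invariants.

    ``violations`` lists one message per offending field.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration: " + "; ".join(self.violations))


class InconsistencyError(QFAError, ValueError):
    """Inputs that must agree (screen ids, backgrounds, labels) do not."""


class InsufficientOverlapError(QFAError, ValueError):
    """Fewer than the required number of ORFs are shared between screens."""


class DegenerateScreenError(QFAError, ValueError):
    """A screen carries no usable signal (e.g. all control fitnesses zero)."""


class DegenerateColumnError(QFAError, ValueError):
    """A profile-matrix column has too few values or zero spread."""


class NoProfileError(QFAError, ValueError):
    """The query gene has no non-missing values in the profile matrix."""


class InvalidInputError(QFAError, ValueError):
    """A numeric input is outside its admissible domain (e.g. p not in [0, 1])."""


class SchemaError(QFAError, ValueError):
    """A tabular file is missing a required column."""


class DataError(QFAError, ValueError):
    """A tabular file contains inconsistent records (keyed by culture)."""


class PipelineError(QFAError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending keys."""

    def __init__(self, stage, message, keys=None):
        self.stage = stage
        self.keys = list(keys) if keys else []
        detail = f"stage '{stage}': {message}"
        if self.keys:
            detail += f" (records: {', '.join(map(str, self.keys[:10]))})"
        super().__init__(detail)
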