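"""Exception hierarchy shared across the package."""


class CvriskvalError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CvriskvalError, ValueError):
    """A numeric argument violates a precondition (e.g. non-positive creatinine)."""


class MissingDataError(CvriskvalError, ValueError):
    """A predictor required by a model specification is absent; names the field(s)."""

    def __init__(self, fields):
        self.fields = tuple(fields)
        super().__init__(f"missing required predictor(s): {', '.join(self.fields)}")


class ConfigError(CvriskvalError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class DataIntegrityError(CvriskvalError, ValueError):
    """Input records contradict each other (e.g. events dated before cohort entry)."""


class UndefinedResultError(CvriskvalError, ValueError):
    """A statistic is undefined on this input (e.g. sensitivity with zero events)."""
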