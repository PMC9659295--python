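"""Exception hierarchy for healthlit."""


class HealthlitError(Exception):
    """Base class for all healthlit errors."""


class SchemaError(HealthlitError):
    """A required column or item id is missing, or a mapping is inconsistent."""


class EmptyInputError(HealthlitError):
    """An input table contains no rows."""


class DegenerateSplitError(HealthlitError):
    """A median split was requested on constant values."""


class EmptySubgroupError(HealthlitError):
    """A covariate filter selected no respondents."""


class ConfigError(HealthlitError):
    """A generator or pipeline configuration value is out of range."""


class EstimationError(HealthlitError):
    """A model could not be estimated (ill-conditioned data, degenerate variance...)."""


class IllConditionedError(EstimationError):
    """Dichotomous data violate the well-conditioned condition for CML.

    Carries a witness partition of the items when available.
    """

    def __init__(self, message, witness=None):
        super().__init__(message)
        self.witness = witness
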