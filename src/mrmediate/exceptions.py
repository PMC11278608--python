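"""Exception hierarchy shared across the package."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """A run configuration or column dialect is unusable."""


class EmptyInputError(MRMediateError):
    """An input table contained no usable rows."""


class EmptyResultError(MRMediateError):
    """A filtering step removed every variant."""


class InsufficientInstrumentsError(MRMediateError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(MRMediateError):
    """Wald ratio requested with a zero exposure effect."""


class UndefinedProportionError(MRMediateError):
    """Proportion mediated requested with a zero total effect."""


class MissingLDError(MRMediateError):
    """A variant required for clumping is absent from the LD matrix."""


class MissingEAFError(MRMediateError):
    """Effect-allele frequency needed but absent."""


class CollinearityError(MRMediateError):
    """Exposure-effect matrix is rank deficient."""


class ScenarioValidationError(MRMediateError):
    """A synthetic scenario specification violated its invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid scenario: " + "; ".join(self.violations))
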