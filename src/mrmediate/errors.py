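"""Typed exceptions shared across the package."""


class MRToolError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRToolError):
    """A configuration file, column map or parameter set is invalid."""


class NoSharedInstrumentsError(MRToolError):
    """Exposure and outcome tables share no variants."""


class NoInstrumentsError(MRToolError):
    """Instrument selection left zero variants.

    Attributes
    ----------
    stage : str
        Name of the first selection stage that produced an empty set
        (``"pvalue"``, ``"clump"`` or ``"fstat"``).
    """

    def __init__(self, stage: str, message: str | None = None):
        self.stage = stage
        super().__init__(message or f"no instruments survive stage '{stage}'")


class InsufficientInstrumentsError(MRToolError):
    """An estimator was given fewer instruments than it requires."""


class UndefinedRatioError(MRToolError):
    """Wald ratio requested with a zero exposure effect."""


class UndefinedProportionError(MRToolError):
    """Mediated proportion requested with a zero total effect."""


class SelfComparisonError(MRToolError):
    """Exposure and outcome refer to the same trait."""


class MediationLegError(MRToolError):
    """One leg of a two-step mediation analysis failed.

    Attributes
    ----------
    leg : str
        Which leg failed: ``"total"``, ``"a"`` or ``"b"``.
    """

    def __init__(self, leg: str, cause: Exception):
        self.leg = leg
        self.cause = cause
        super().__init__(f"mediation leg '{leg}' failed: {cause}")
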