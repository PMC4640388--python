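"""Exception hierarchy for ydrisk."""


class YdriskError(Exception):
    """Base class for all ydrisk errors."""


class ParameterError(YdriskError, ValueError):
    """A risk-model parameter is invalid (bad RR, prevalence, cutpoints ...)."""


class SchemaError(YdriskError, ValueError):
    """An input table does not conform to the declared schema."""


class MissingFactorError(YdriskError, ValueError):
    """A profile lacks a level for a factor that applies to it.

    Subjects with missing risk-factor data are excluded from analysis by
    default; imputation of the reference level is an explicit opt-in.
    """
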