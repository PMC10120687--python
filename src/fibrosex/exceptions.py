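"""Exception hierarchy for fibrosex."""


class FibrosexError(Exception):
    """Base class for all fibrosex errors."""


class RuleParseError(FibrosexError):
    """A logic rule string does not match the grammar ``[!]A & [!]B => C``."""


class ModelValidationError(FibrosexError):
    """A network model violates a structural invariant (bad reference,
    duplicate id, parameter out of range)."""


class ParameterError(FibrosexError):
    """A numeric parameter is outside its admissible domain (e.g. EC50
    outside (0,1), degenerate Hill normalization)."""


class IntegrationError(FibrosexError):
    """The ODE solver failed or produced out-of-bounds activities."""


class ProtocolError(FibrosexError):
    """A simulation protocol was configured inconsistently (unknown
    stimulus/treatment/condition, empty record set, mismatched panels)."""
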