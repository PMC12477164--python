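"""Exception types shared across the pipeline."""


class SilicoTrialError(Exception):
    """Base class for all package errors."""


class ParameterError(SilicoTrialError, ValueError):
    """An argument or configuration value is out of its legal range."""


class FormatError(SilicoTrialError, ValueError):
    """An input file does not conform to the expected dialect."""


class StructuralError(SilicoTrialError, ValueError):
    """The network / knowledge-set geometry cannot support the request
    (empty neighborhood, unreachable response layer, exhausted candidates)."""
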