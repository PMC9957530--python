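"""Exception hierarchy for pcitnet."""


class PcitnetError(Exception):
    """Base class for all pcitnet errors."""


class ConfigurationError(PcitnetError, ValueError):
    """A configuration field is missing, unknown, or out of range."""


class ValidationError(PcitnetError, ValueError):
    """Input data violate a documented contract (schema, range, shape)."""


class PipelineError(PcitnetError, RuntimeError):
    """A pipeline stage failed; the message names the stage and a hint."""
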