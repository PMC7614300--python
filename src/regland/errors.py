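"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An invalid parameter value; the message names the offending field."""


class ValidationError(ValueError):
    """Input data violated a structural contract (sorting, ids, ranges)."""
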