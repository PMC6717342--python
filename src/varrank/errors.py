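"""Exception hierarchy shared across the pipeline stages."""


class VarrankError(Exception):
    """Base class for all pipeline errors."""


class LoadError(VarrankError):
    """A file could not be parsed into a valid domain object."""


class ConfigurationError(VarrankError):
    """Inputs are individually valid but inconsistent with each other."""


class ValidationError(VarrankError):
    """A domain object violates one of its invariants."""
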