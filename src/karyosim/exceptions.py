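"""Exception types shared across the package."""


class KaryosimError(Exception):
    """Base class for all karyosim errors."""


class ConfigurationError(KaryosimError, ValueError):
    """A configuration value is missing, malformed or violates an invariant."""


class DomainError(KaryosimError, ValueError):
    """An operation was called outside its domain (precondition violation)."""
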