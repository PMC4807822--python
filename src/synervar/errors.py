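"""Exception hierarchy shared across the pipeline stages."""


class SynervarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynervarError):
    """A configuration value is out of its valid range."""


class InputError(SynervarError):
    """Malformed or inconsistent input data."""


class NumericalError(SynervarError):
    """A computation could not be carried out (singularity, degeneracy)."""
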