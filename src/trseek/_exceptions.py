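"""Exception hierarchy shared across trseek modules."""


class TrseekError(Exception):
    """Base class for all trseek errors."""


class FormatError(TrseekError):
    """An input file violates the expected on-disk format."""


class ConfigError(TrseekError):
    """A configuration value or combination is invalid."""


class ValidationError(TrseekError):
    """Data violate an invariant required by the pipeline."""
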