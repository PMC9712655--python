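"""Exception types shared across the package."""


class SteroidQsarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SteroidQsarError):
    """An invalid configuration value; the message names the offending field."""


class InputError(SteroidQsarError):
    """Malformed or inconsistent user-supplied input."""


class PipelineError(SteroidQsarError):
    """A pipeline stage produced an unusable state (e.g. every descriptor dropped)."""
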