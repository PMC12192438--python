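"""Exception types shared across the pipeline.

``InputError`` marks malformed or inconsistent data (bad rows, impossible
counts); ``ConfigError`` marks an invalid configuration or an unknown mode.
Both derive from ``GvShuttleError`` so callers can catch everything at once.
"""


class GvShuttleError(Exception):
    """Base class for all gvshuttle errors."""


class InputError(GvShuttleError):
    """Malformed or internally inconsistent input data."""


class ConfigError(GvShuttleError):
    """Invalid configuration value or unknown mode/category."""
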