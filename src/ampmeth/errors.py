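"""Exception hierarchy shared across the package."""


class AmpmethError(Exception):
    """Base class for all errors raised by ampmeth."""


class ConfigError(AmpmethError):
    """Invalid run/design configuration (maps to CLI exit code 2)."""


class PanelError(AmpmethError):
    """Malformed panel configuration."""


class SequenceError(PanelError):
    """A sequence contains characters outside A/C/G/T or is otherwise unusable."""


class ValidationError(PanelError):
    """A panel, sheet or design invariant is violated."""
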