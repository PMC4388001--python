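"""Exception hierarchy.

All coansel errors derive from :class:`CoanselError`; argument/state errors
additionally subclass the matching builtin so callers can catch either.
"""


class CoanselError(Exception):
    """Base class for all coansel errors."""


class InvalidArgumentError(CoanselError, ValueError):
    """A caller-supplied value is outside the operation's domain."""


class InvalidStateError(CoanselError, RuntimeError):
    """The simulation state cannot support the requested operation."""


class PedigreeError(CoanselError, ValueError):
    """Malformed pedigree: duplicate ids, missing parents, or cycles."""


class NumericalError(CoanselError, RuntimeError):
    """A linear-algebra step failed (singular system, divergent chain)."""


class ConfigError(CoanselError, ValueError):
    """A configuration file contains unknown keys or out-of-range values."""
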