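"""Exception hierarchy shared across the package.

All errors raised by hingemd derive from :class:`HingemdError` so callers
can catch the package's failures with a single except clause while still
distinguishing file-format problems from bad geometry or bad configs.
"""


class HingemdError(Exception):
    """Base class for all hingemd errors."""


class FormatError(HingemdError):
    """A structure or trajectory file violates its format contract."""


class TopologyError(HingemdError):
    """Atom counts or atom identities disagree between inputs."""


class SelectionError(HingemdError):
    """An atom-selection expression could not be parsed."""


class DomainError(HingemdError):
    """Input values are outside the mathematical domain of an operation
    (empty atom sets, degenerate geometry, mismatched index sets...)."""


class ConfigError(HingemdError):
    """An analysis configuration value is invalid or inconsistent."""
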