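"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`CytobinError` so the
CLI can map any library error to a nonzero exit with a stage-tagged message.
"""


class CytobinError(Exception):
    """Base class for all cytobin errors."""


class InputError(CytobinError):
    """A file could not be read or parsed (message names the path)."""


class FormatError(CytobinError):
    """A file parsed but violates a structural invariant (e.g. duplicate channels)."""


class ConfigError(CytobinError):
    """A parameter, marker name, cutoff or spec value is invalid or missing."""


class EmptyInputError(CytobinError):
    """An operation that requires at least one event received none."""
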