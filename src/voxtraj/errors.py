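"""Exception hierarchy for voxtraj.

All package-specific failures derive from :class:`VoxtrajError` so callers
can catch one base class.  The CLI maps subclasses onto exit codes.
"""


class VoxtrajError(Exception):
    """Base class for all voxtraj errors."""


class InvalidArgumentError(VoxtrajError, ValueError):
    """A function argument violates its contract (bad shape, range, name)."""


class ConfigurationError(VoxtrajError):
    """A geometry/parameter combination is inconsistent.

    The canonical case: the grid buffer is smaller than the kernel cutoff or
    the observer's receptive-field radius, which would reintroduce edge
    artifacts into the central region.
    """


class UnsupportedFormatError(VoxtrajError):
    """Unknown trajectory format tag."""


class CorruptInputError(VoxtrajError):
    """An input file violates its own format contract (e.g. atom-count
    mismatch between a coordinate frame and the topology)."""


class SelectionSyntaxError(VoxtrajError):
    """The focus-selection expression does not parse; the message names the
    offending token."""


class UnknownPropertyError(VoxtrajError, KeyError):
    """Requested atom-property channel is not registered."""


class RegistrationError(VoxtrajError):
    """Feature registration failed (duplicate tag, empty run, ...)."""


class SchemaError(VoxtrajError):
    """An HDF store operation violates the dataset schema (shape mismatch,
    ragged record counts in strict mode)."""
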