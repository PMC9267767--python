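"""Exception hierarchy for verbgen.

All package-specific failures derive from :class:`VerbgenError` so callers
can catch one base class at CLI boundaries.
"""


class VerbgenError(Exception):
    """Base class for all verbgen errors."""


class FormatError(VerbgenError):
    """A file does not conform to the expected tabular or vector format."""


class IntegrityError(VerbgenError):
    """Input data violates a uniqueness or consistency constraint."""


class ConfigError(VerbgenError):
    """A configuration object is incomplete or self-contradictory."""


class StateError(VerbgenError):
    """An operation was called on data in the wrong state (e.g. uncoded trials)."""


class EmptyDistributionError(StateError):
    """No verb responses available to build a response distribution."""
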