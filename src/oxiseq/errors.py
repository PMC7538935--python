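"""Exception hierarchy for oxiseq.

All failures raised by the package derive from :class:`OxiseqError`, split by
what went wrong: the *shape/content* of data (:class:`ValidationError`), the
*format* of an external file (:class:`FormatError`), or the *wiring* of the
run — missing samples, impossible designs, bad option values
(:class:`ConfigurationError`).
"""


class OxiseqError(Exception):
    """Base class for all oxiseq errors."""


class ValidationError(OxiseqError):
    """Data violates an invariant (negative count, duplicate label, ...)."""


class FormatError(OxiseqError):
    """An external file does not conform to its expected format."""


class ConfigurationError(OxiseqError):
    """The requested analysis cannot be wired from the given inputs/options."""
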