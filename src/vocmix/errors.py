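"""Exception hierarchy.

All package errors derive from :class:`VocmixError`; the CLI maps any of
them to exit code 2 (validation failure) as opposed to unexpected crashes.
"""


class VocmixError(Exception):
    """Base class for all vocmix errors."""


class FormatError(VocmixError):
    """A file does not have the expected structure (e.g. missing column)."""


class ParseError(VocmixError):
    """A cell value could not be interpreted (carries the offending row)."""


class DuplicateRecordError(VocmixError):
    """The same (salon, worker, chemical) appeared more than once."""


class ValidationError(VocmixError):
    """A value violates a domain invariant (e.g. nonpositive limit)."""


class DomainError(VocmixError):
    """An operation was called outside its mathematical domain."""
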