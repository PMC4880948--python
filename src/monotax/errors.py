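"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`MonotaxError`, so callers (and the CLI) can distinguish bad input
from genuine bugs.
"""

from __future__ import annotations


class MonotaxError(Exception):
    """Base class for all errors raised by monotax."""


class NewickParseError(MonotaxError):
    """Structurally invalid Newick text.

    ``offset`` is the 0-based character offset of the first offending
    character when it is known, else ``None``.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (at character {offset})")
        self.offset = offset


class FormatError(MonotaxError):
    """A file or string violates the expected layout (columns, markers, tokens)."""


class DataError(MonotaxError):
    """Well-formed input carrying inadmissible content (duplicates, bad names)."""


class ConstraintError(MonotaxError):
    """A domain rule is violated, e.g. a lineage rewrite that renames a species."""


class TaxonLookupError(MonotaxError):
    """A queried taxon or node does not exist; ``candidates`` lists near-misses."""

    def __init__(self, message: str, candidates: list[str] | None = None):
        if candidates:
            message = f"{message}; close matches: {', '.join(candidates)}"
        super().__init__(message)
        self.candidates = candidates or []


class ArgumentError(MonotaxError):
    """An operation was called with an argument outside its contract."""
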