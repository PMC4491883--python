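"""Exception hierarchy.

Everything raised deliberately by pathpaint derives from :class:`PathPaintError`
so callers can catch the library's failures with a single except clause.
"""


class PathPaintError(Exception):
    """Base class for all pathpaint errors."""


class ValidationError(PathPaintError):
    """A diagram or document violates a structural invariant."""


class RefError(PathPaintError):
    """An identifier does not resolve (unknown node, compartment, shape, ...)."""


class DuplicateError(PathPaintError):
    """An entity that must be unique already exists."""


class ConflictError(PathPaintError):
    """An operation conflicts with existing state (e.g. a second channel link)."""


class SchemaError(PathPaintError):
    """A document does not match the expected schema; message names the path."""


class DataError(PathPaintError):
    """Tabular data is inconsistent (duplicate keys, values out of index)."""


class ParseError(PathPaintError):
    """A file could not be parsed; message locates the offending row/element."""


class ContractError(PathPaintError):
    """An operation was called outside its contract (bad argument combination)."""


class LayoutError(PathPaintError):
    """Automatic layout cannot satisfy its guarantees (compartment too small)."""


class CapabilityError(PathPaintError):
    """The request exceeds what the implementation supports (e.g. attractor
    enumeration beyond 20 nodes)."""
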