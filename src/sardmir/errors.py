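"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SardmirError`, so callers can catch one type at the CLI boundary.
"""


class SardmirError(Exception):
    """Base class for all errors raised by sardmir."""


class AlphabetError(SardmirError, ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class DomainError(SardmirError, ValueError):
    """An argument is outside the domain an operation is defined on."""


class CoordinateError(SardmirError, ValueError):
    """Genomic or structural coordinates fall outside their sequence."""


class AnatomyError(SardmirError, ValueError):
    """A secondary structure lacks the feature being asked for (e.g. no stem)."""


class CatalogParseError(SardmirError, ValueError):
    """A catalog fixture row is malformed; the message names the row."""


class CatalogIntegrityError(SardmirError, ValueError):
    """A catalog fixture fails a whole-file check (e.g. wrong record count)."""


class PlacementError(SardmirError, ValueError):
    """Synthetic implants cannot be placed as requested (overlap / no room)."""
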