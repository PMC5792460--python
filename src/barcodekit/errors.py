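"""Exception hierarchy for barcodekit.

All exceptions derive from :class:`BarcodekitError` so callers can catch
library failures without masking programming errors.
"""


class BarcodekitError(Exception):
    """Base class for all barcodekit errors."""


class FormatError(BarcodekitError):
    """A file could not be parsed (empty, malformed, illegal characters)."""


class AlignmentError(BarcodekitError):
    """Sequences that must be aligned have unequal lengths."""


class ValidationError(BarcodekitError):
    """Library-level consistency violation (duplicate ids, orphan rows)."""


class InsufficientDataError(BarcodekitError):
    """Too few sequences/pairs/taxa for the requested analysis."""


class UndefinedDistanceError(BarcodekitError):
    """A pairwise distance is undefined (saturated K2P or too little overlap)."""


class IncompleteMatrixError(BarcodekitError):
    """A distance matrix with undefined entries was passed where a complete
    one is required (e.g. neighbor joining); prune or impute first."""


class InsufficientTaxaError(BarcodekitError):
    """Fewer than three taxa: no unrooted tree can be built."""
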