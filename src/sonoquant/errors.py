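"""Exception hierarchy shared across the pipeline stages."""


class SonoquantError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(SonoquantError):
    """Raised for file extensions or pixel layouts the reader does not handle."""


class ImageReadError(SonoquantError):
    """Raised when a file exists but cannot be decoded."""


class ScanCodeError(SonoquantError):
    """Raised when a filename carries no recognizable scan-type code."""


class TemplateLibraryError(SonoquantError):
    """Raised for malformed template library directories or manifests."""


class EmptyROIError(SonoquantError):
    """Raised when no supra-threshold pixel exists in a scan direction."""


class DataError(SonoquantError):
    """Raised for non-finite or otherwise unusable pixel data."""


class DegenerateTemplateError(SonoquantError):
    """Raised for zero-variance template patches (correlation undefined)."""


class TemplateSizeError(SonoquantError):
    """Raised when a patch is not strictly smaller than the searched image."""


class OrderingError(SonoquantError):
    """Raised when structure depths violate the superficial-to-deep order."""


class EllipseFitError(SonoquantError):
    """Raised when the direct least-squares conic fit has no ellipse solution."""


class ContractError(SonoquantError):
    """Raised when an internal numeric contract is violated (e.g. an
    un-normalized co-occurrence matrix is passed where probabilities are
    expected)."""


class EmptyRecordError(SonoquantError):
    """Raised when no structure at all was detected for an image."""


class PhantomSpecError(SonoquantError):
    """Raised for geometrically inconsistent phantom specifications."""


class UsageError(SonoquantError):
    """Raised for invalid batch/agreement invocations (empty input
    directory, disjoint measurement keys, ...)."""
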