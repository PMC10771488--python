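"""Exception hierarchy.

All failures that originate from malformed user input derive from
:class:`FossilFluorError` so callers (and the CLI) can distinguish them
from programming errors.
"""


class FossilFluorError(Exception):
    """Base class for all package-specific errors."""


class AxisError(FossilFluorError, ValueError):
    """A spectral axis is malformed or two axes do not match."""


class EmptyROIError(FossilFluorError, ValueError):
    """A polygon ROI rasterizes to zero pixels on the given stack."""


class EmptyBandError(FossilFluorError, ValueError):
    """A wavelength band contains no channel centers."""


class SingularDesignError(FossilFluorError, ValueError):
    """The endmember matrix is rank deficient; abundances are not identifiable."""


class CollinearityError(SingularDesignError):
    """Two finalized endmember spectra are (near-)proportional."""

    def __init__(self, msg: str, pair: tuple[str, str] | None = None):
        super().__init__(msg)
        self.pair = pair


class ConvergenceError(FossilFluorError, RuntimeError):
    """An iterative solver exceeded its iteration cap."""


class DecompositionError(FossilFluorError, RuntimeError):
    """The substrate-plus-Gaussians fit failed to converge."""

    def __init__(self, msg: str, diagnostics: dict | None = None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


class FormatError(FossilFluorError, ValueError):
    """A file on disk violates the documented layout.

    Carries the offending path and, where known, the field at fault.
    """

    def __init__(self, msg: str, path=None, field: str | None = None):
        detail = msg
        if path is not None:
            detail = f"{path}: {detail}"
        if field is not None:
            detail = f"{detail} (field: {field})"
        super().__init__(detail)
        self.path = path
        self.field = field


class IncompatibleTilesError(FossilFluorError, ValueError):
    """Abundance-map tiles cannot be stitched (names/constraint mismatch)."""


class InsufficientPixelsError(FossilFluorError, ValueError):
    """A region is too small for the requested statistic."""
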