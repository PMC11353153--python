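"""Exception hierarchy for the fluopipe pipeline."""


class FluoPipeError(Exception):
    """Base class for all fluopipe-specific errors."""


class LoadError(FluoPipeError):
    """An input file could not be read (corrupt page, bad layout, ...)."""


class UnsupportedFormatError(LoadError):
    """The file layout is recognised but not supported (e.g. >2 channels)."""


class SessionFormatError(FluoPipeError):
    """A session container has the wrong magic or schema version."""

    def __init__(self, message, found=None, expected=None):
        super().__init__(message)
        self.found = found
        self.expected = expected


class AlignmentError(FluoPipeError):
    """Ephys recording and imaging session do not overlap in time."""


class MarkerNotFoundError(FluoPipeError):
    """A requested marker tag is absent from the ephys recording."""


class AmbiguousMarkerError(FluoPipeError):
    """A marker tag occurs more than once; occurrences listed in message."""


class ROIImportError(FluoPipeError):
    """ROIs from another session cannot be placed on this image."""


class AnnotationImportError(FluoPipeError):
    """An annotation file references ROI ids absent from the manifest."""


class StageNotRunError(FluoPipeError):
    """A report or downstream step requires a pipeline stage not yet run."""

    def __init__(self, stage):
        super().__init__(f"pipeline stage not run: {stage!r}")
        self.stage = stage


class CatalogueError(FluoPipeError):
    """An unknown batch operation name; valid names listed in message."""


class GenerationError(FluoPipeError):
    """Synthetic-data parameters are infeasible (geometry, Nyquist, ...)."""
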