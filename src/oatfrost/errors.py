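"""Exception hierarchy for the oatfrost pipeline."""


class OatfrostError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OatfrostError):
    """A parameter or configuration value is outside its documented range."""


class InvalidImageError(OatfrostError):
    """Raster input contains non-finite or out-of-range values."""


class EmptyHistogramError(OatfrostError):
    """Histogram has zero total mass; no threshold is defined."""


class DegenerateHistogramError(OatfrostError):
    """All histogram mass sits at a single level; thresholding is undefined."""


class ThresholdCountError(OatfrostError):
    """Fewer thresholds than requested could be placed.

    ``partial`` carries the thresholds found before the failure.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class CannotSplitError(OatfrostError):
    """More classes were requested than the merger produced; the method only merges."""


class CorruptInputError(OatfrostError):
    """A label map or coded image contains values outside the declared range."""


class GeometryError(OatfrostError):
    """A polygon rasterizes to an empty or out-of-bounds pixel set."""


class PlacementError(OatfrostError):
    """Could not place the requested number of sample polygons.

    ``partial`` carries the polygons placed before giving up.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


class UndefinedAccuracyError(OatfrostError):
    """Accuracy requested from an empty matrix row, column, or grand total."""
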