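"""Exception hierarchy for the fundus-wssh pipeline.

All parameter/contract violations derive from :class:`FundusError` so callers
can catch pipeline errors without swallowing programming errors.
"""


class FundusError(Exception):
    """Base class for all fundus-wssh errors."""


class InvalidParameterError(FundusError, ValueError):
    """A numeric or categorical parameter is outside its documented domain."""


class InvalidColorSpaceError(FundusError, ValueError):
    """Operation received an image in the wrong color space."""


class ShapeError(FundusError, ValueError):
    """Array shapes are incompatible with the operation's contract."""


class OutOfRangeError(FundusError, ValueError):
    """Pixel values fall outside the declared value range."""


class NoDiscFoundError(FundusError, RuntimeError):
    """The circular accumulator found no optic-disc candidate above the floor."""


class InvalidDatasetError(FundusError, ValueError):
    """The training dataset violates a precondition (e.g. a single class)."""


class InvalidROIError(FundusError, ValueError):
    """A region of interest lies outside the image or is degenerate."""


class UndefinedGroundTruthError(FundusError, ValueError):
    """An evaluation metric was asked for with empty ground truth."""


class PipelineConfigError(FundusError, ValueError):
    """The pipeline configuration is malformed (unknown keys, bad types)."""


class ImageIOError(FundusError, OSError):
    """An image file could not be read or written."""
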